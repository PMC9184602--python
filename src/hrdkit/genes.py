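"""Packaged HRR gene lists and gene coordinates.

BRCA1 and BRCA2 have a special role in the tumor classification (they
define classes H1a/H2a) and are therefore kept out of every "other HRR
genes" list. Two lists ship with the package: a concise 20-gene list and
an extended 140-gene list; both are plain text files users can edit or
replace with a custom list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .io_errors import ValidationError

BRCA_GENES = frozenset({"BRCA1", "BRCA2"})

_LIST_RESOURCES = {"short": "genes_short.txt", "long": "genes_long.txt"}


@dataclass(frozen=True)
class GeneList:
    """A named set of other-HRR gene symbols plus optional coordinates.

    ``coords`` maps gene -> (chromosome, start, end), 1-based inclusive;
    genes without coordinates are skipped (with a warning) by operations
    that need positions, such as homozygous-deletion calling.
    """

    name: str
    symbols: frozenset[str]
    coords: pd.DataFrame = field(default_factory=pd.DataFrame)  # gene, chromosome, start, end

    def __post_init__(self) -> None:
        overlap = self.symbols & BRCA_GENES
        if overlap:
            raise ValidationError(
                f"BRCA1/BRCA2 must not appear in an other-HRR gene list: {sorted(overlap)}"
            )

    def __contains__(self, gene: str) -> bool:
        return gene in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)

    def coordinates(self, gene: str) -> tuple[str, int, int] | None:
        if len(self.coords) == 0:
            return None
        row = self.coords[self.coords["gene"] == gene]
        if len(row) == 0:
            return None
        r = row.iloc[0]
        return (str(r["chromosome"]), int(r["start"]), int(r["end"]))


def _read_symbols(text: str) -> list[str]:
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def gene_coordinates() -> pd.DataFrame:
    """Packaged coordinates for BRCA1/2 and the concise-list genes."""
    with resources.files("hrdkit.data").joinpath("gene_coords.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_gene_list(name_or_path: str = "long") -> GeneList:
    """Load a packaged ("short"/"long") or custom (file path) gene list."""
    if name_or_path in _LIST_RESOURCES:
        text = (
            resources.files("hrdkit.data")
            .joinpath(_LIST_RESOURCES[name_or_path])
            .read_text()
        )
        name = name_or_path
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise ValidationError(
                f"gene list {name_or_path!r} is neither packaged (short/long) nor a file"
            )
        text = path.read_text()
        name = path.stem
    symbols = frozenset(_read_symbols(text)) - BRCA_GENES
    coords = gene_coordinates()
    return GeneList(name=name, symbols=symbols, coords=coords)
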