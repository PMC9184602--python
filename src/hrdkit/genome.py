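"""Genome build: chromosome lengths and centromere intervals.

Coordinates are 1-based inclusive throughout the package (the convention
of allele-specific copy-number callers whose segment tables we consume).
A chromosome arm is everything strictly before (p) or strictly after (q)
the centromere interval; telomere ends are position 1 and the chromosome
length.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

from .io_errors import ValidationError

_DEFAULT_BUILD_RESOURCE = "genome_grch38_autosomes.tsv"


@dataclass(frozen=True)
class Arm:
    """One chromosome arm, 1-based inclusive bounds."""

    chromosome: str
    name: str  # "p" or "q"
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths plus centromere intervals.

    Invariants: 0 < centromere_start < centromere_end < length for every
    chromosome; chromosome names are unique.
    """

    table: pd.DataFrame  # columns: chrom, length, centromere_start, centromere_end

    def __post_init__(self) -> None:
        required = ["chrom", "length", "centromere_start", "centromere_end"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"genome build missing columns: {missing}")
        if len(self.table) == 0:
            raise ValidationError("genome build must contain at least one chromosome")
        if self.table["chrom"].duplicated().any():
            dups = self.table.loc[self.table["chrom"].duplicated(), "chrom"].tolist()
            raise ValidationError(f"duplicate chromosome names: {dups}")
        bad = self.table[
            ~(
                (0 < self.table["centromere_start"])
                & (self.table["centromere_start"] < self.table["centromere_end"])
                & (self.table["centromere_end"] < self.table["length"])
            )
        ]
        if len(bad):
            raise ValidationError(
                "invalid chromosome geometry (need 0 < centromere_start < "
                f"centromere_end < length): {bad['chrom'].tolist()}"
            )
        object.__setattr__(self, "_index", self.table.set_index("chrom"))

    @property
    def chromosomes(self) -> list[str]:
        return self.table["chrom"].tolist()

    def length(self, chrom: str) -> int:
        return int(self._index.at[chrom, "length"])

    def centromere(self, chrom: str) -> tuple[int, int]:
        return (
            int(self._index.at[chrom, "centromere_start"]),
            int(self._index.at[chrom, "centromere_end"]),
        )

    def arms(self, chrom: str | None = None) -> Iterator[Arm]:
        """Yield p and q arms, for one chromosome or genome-wide."""
        chroms = [chrom] if chrom is not None else self.chromosomes
        for c in chroms:
            cen_start, cen_end = self.centromere(c)
            yield Arm(c, "p", 1, cen_start - 1)
            yield Arm(c, "q", cen_end + 1, self.length(c))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index.index


def default_build() -> GenomeBuild:
    """The packaged 22-autosome GRCh38-like build."""
    with resources.files("hrdkit.data").joinpath(_DEFAULT_BUILD_RESOURCE).open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return GenomeBuild(table)


def read_genome_build(path: str | Path | None = None) -> GenomeBuild:
    """Read a genome build TSV (chrom, length, centromere_start, centromere_end).

    With ``path=None`` the packaged default autosome build is returned.
    """
    if path is None:
        return default_build()
    try:
        table = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse genome build {path}: {exc}") from exc
    required = ["chrom", "length", "centromere_start", "centromere_end"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"genome build {path} missing columns: {missing}")
    for col in required[1:]:
        bad = table[pd.to_numeric(table[col], errors="coerce").isna()]
        if len(bad):
            raise ValidationError(
                f"genome build {path}: non-numeric {col} at line(s) "
                f"{(bad.index + 2).tolist()}"
            )
        table[col] = table[col].astype(int)
    return GenomeBuild(table)
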