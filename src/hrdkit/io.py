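"""Readers and writers for the tab-delimited exchange formats.

Formats (all 1-based inclusive coordinates):

* segments: ``sample  chromosome  start  end  nMajor  nMinor``
* variants (MAF-like dialect): ``sample  gene  chromosome  position  ref
  alt  variant_classification  origin  t_alt_count  t_ref_count
  db_annotations`` where ``db_annotations`` is a semicolon-separated list
  of ``source:assessment`` pairs (may be empty) and ``origin`` is
  ``germline`` or ``somatic``
* methylation: probe x sample beta-value matrix, first column ``probe``
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .io_errors import ValidationError
from .segments import SEGMENT_COLUMNS, SegmentProfile, profiles_to_table

log = logging.getLogger(__name__)

VARIANT_COLUMNS = [
    "sample",
    "gene",
    "chromosome",
    "position",
    "ref",
    "alt",
    "variant_classification",
    "origin",
    "t_alt_count",
    "t_ref_count",
    "db_annotations",
]

#: accepted database assessment vocabulary (normalized, lower case)
DB_ASSESSMENTS = {
    "pathogenic",
    "likely_pathogenic",
    "uncertain_significance",
    "likely_benign",
    "benign",
}


def read_segments(path: str | Path) -> list[SegmentProfile]:
    """Read an ASCAT-like segment table into per-sample profiles.

    nMajor/nMinor are swapped when given in the wrong order, then
    validated (non-negative, non-overlapping).
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    required = ["sample", "chromosome", "start", "end", "nMajor", "nMinor"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"segment file {path} missing columns: {missing}")
    if (table[["nMajor", "nMinor"]] < 0).any().any():
        bad = table[(table[["nMajor", "nMinor"]] < 0).any(axis=1)].index[0]
        raise ValidationError(f"segment file {path}: negative copy number at line {bad + 2}")
    a = table[["nMajor", "nMinor"]].max(axis=1)
    b = table[["nMajor", "nMinor"]].min(axis=1)
    tidy = pd.DataFrame(
        {
            "sample": table["sample"].astype(str),
            "chromosome": table["chromosome"].astype(str),
            "start": table["start"].astype(int),
            "end": table["end"].astype(int),
            "a": a.astype(int),
            "b": b.astype(int),
        }
    )
    profiles = []
    for sample, grp in tidy.groupby("sample", sort=True):
        profiles.append(SegmentProfile(str(sample), grp.drop(columns="sample")))
    return profiles


def write_segments(profiles: list[SegmentProfile], path: str | Path) -> None:
    table = profiles_to_table(profiles).rename(columns={"a": "nMajor", "b": "nMinor"})
    with open(path, "w") as fh:
        fh.write("# 1-based inclusive coordinates; nMajor >= nMinor\n")
        table.to_csv(fh, sep="\t", index=False)


def parse_db_annotations(raw: str | float | None) -> list[tuple[str, str]]:
    """Parse ``source:assessment;source:assessment`` into pairs."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
        return []
    pairs = []
    for token in str(raw).split(";"):
        token = token.strip()
        if not token:
            continue
        if ":" not in token:
            raise ValidationError(f"malformed db annotation token {token!r}")
        source, assessment = token.split(":", 1)
        assessment = assessment.strip().lower().replace(" ", "_")
        if assessment in ("vus", "uncertain"):
            assessment = "uncertain_significance"
        if assessment not in DB_ASSESSMENTS:
            raise ValidationError(
                f"unknown db assessment {assessment!r} (expected one of {sorted(DB_ASSESSMENTS)})"
            )
        pairs.append((source.strip(), assessment))
    return pairs


def read_variants(path: str | Path) -> pd.DataFrame:
    """Read the MAF-like variant table.

    Adds a ``vaf`` column (alt / (alt + ref)) and a ``db_assessments``
    column holding parsed (source, assessment) pairs.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"db_annotations": str})
    missing = [c for c in VARIANT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"variant file {path} missing columns: {missing}")
    table = table.copy()
    table["origin"] = table["origin"].astype(str).str.lower()
    bad_origin = ~table["origin"].isin(["germline", "somatic"])
    if bad_origin.any():
        tok = table.loc[bad_origin, "origin"].iloc[0]
        raise ValidationError(f"variant file {path}: unknown origin {tok!r}")
    alt = table["t_alt_count"].astype(float)
    ref = table["t_ref_count"].astype(float)
    total = alt + ref
    zero_somatic = (total == 0) & (table["origin"] == "somatic")
    if zero_somatic.any():
        raise ValidationError(
            f"variant file {path}: somatic record with zero read depth at line "
            f"{table.index[zero_somatic][0] + 2}"
        )
    with np.errstate(invalid="ignore"):
        table["vaf"] = np.where(total > 0, alt / total, np.nan)
    table["db_assessments"] = table["db_annotations"].map(parse_db_annotations)
    return table


def write_variants(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in VARIANT_COLUMNS if c in table.columns]
    with open(path, "w") as fh:
        fh.write("# 1-based positions; db_annotations: source:assessment;...\n")
        table[cols].to_csv(fh, sep="\t", index=False)


def read_methylation(path: str | Path) -> pd.DataFrame:
    """Read a probe x sample beta matrix; betas must lie in [0, 1].

    Missing cells stay missing (NaN) — they are never coerced to zero.
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    first = table.columns[0]
    if first != "probe":
        raise ValidationError(f"methylation file {path}: first column must be 'probe'")
    matrix = table.set_index("probe")
    matrix = matrix.apply(pd.to_numeric, errors="coerce")
    values = matrix.to_numpy(dtype=float)
    out_of_range = (values < 0) | (values > 1)
    if np.nansum(out_of_range) > 0:
        i, j = np.argwhere(out_of_range)[0]
        raise ValidationError(
            f"methylation file {path}: beta {values[i, j]} outside [0, 1] "
            f"(probe {matrix.index[i]}, sample {matrix.columns[j]})"
        )
    return matrix


def write_methylation(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "probe"
    out.to_csv(path, sep="\t")


def read_purity(path: str | Path) -> pd.Series:
    """Read a two-column ``sample  purity`` table."""
    table = pd.read_csv(path, sep="\t", comment="#")
    if not {"sample", "purity"} <= set(table.columns):
        raise ValidationError(f"purity file {path} must have columns sample, purity")
    purity = table.set_index("sample")["purity"].astype(float)
    if ((purity <= 0) | (purity > 1)).any():
        raise ValidationError(f"purity file {path}: purity must be in (0, 1]")
    return purity
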