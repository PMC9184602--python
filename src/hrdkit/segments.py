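"""Allele-specific copy-number segment profiles.

A profile is one sample's set of segments, each carrying the major (A)
and minor (B) allele copy numbers with A >= B >= 0 and total copy number
CN = A + B. Coordinates are 1-based inclusive and segments must not
overlap within a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_errors import ValidationError

SEGMENT_COLUMNS = ["chromosome", "start", "end", "a", "b"]


@dataclass
class SegmentProfile:
    """Per-sample allele-specific segments.

    ``segments`` columns: chromosome, start, end, a, b (a = major copy
    number, b = minor). Rows are sorted by chromosome then start.
    """

    sample: str
    segments: pd.DataFrame

    def __post_init__(self) -> None:
        seg = self.segments
        missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
        if missing:
            raise ValidationError(f"profile {self.sample}: missing columns {missing}")
        seg = seg[SEGMENT_COLUMNS].copy()
        for col in ("start", "end", "a", "b"):
            seg[col] = seg[col].astype(int)
        if (seg[["a", "b"]] < 0).any().any():
            raise ValidationError(f"profile {self.sample}: negative copy number")
        if (seg["a"] < seg["b"]).any():
            raise ValidationError(
                f"profile {self.sample}: major < minor copy number (reader should swap)"
            )
        if (seg["start"] > seg["end"]).any():
            bad = seg[seg["start"] > seg["end"]].iloc[0]
            raise ValidationError(
                f"profile {self.sample}: start > end at "
                f"{bad['chromosome']}:{bad['start']}-{bad['end']}"
            )
        seg = seg.sort_values(["chromosome", "start"], kind="mergesort").reset_index(drop=True)
        prev = seg.groupby("chromosome", sort=False)["end"].shift()
        overlap = seg["start"] <= prev
        if overlap.any():
            bad = seg[overlap].iloc[0]
            raise ValidationError(
                f"profile {self.sample}: overlapping segments at "
                f"{bad['chromosome']}:{bad['start']}-{bad['end']}"
            )
        self.segments = seg

    def copy(self) -> "SegmentProfile":
        return SegmentProfile(self.sample, self.segments.copy())

    def locus_state(self, chromosome: str, position: int) -> tuple[int, int] | None:
        """(A, B) of the segment containing the position, or None."""
        seg = self.segments
        hit = seg[
            (seg["chromosome"] == chromosome)
            & (seg["start"] <= position)
            & (seg["end"] >= position)
        ]
        if len(hit) == 0:
            return None
        row = hit.iloc[0]
        return int(row["a"]), int(row["b"])

    def overlapping(self, chromosome: str, start: int, end: int) -> pd.DataFrame:
        seg = self.segments
        return seg[
            (seg["chromosome"] == chromosome) & (seg["start"] <= end) & (seg["end"] >= start)
        ]

    def splice(self, chromosome: str, start: int, end: int, a: int, b: int) -> "SegmentProfile":
        """Return a copy with [start, end] forced to state (a, b).

        Existing segments overlapping the interval are truncated (or split
        when they extend on both sides) and the new segment is inserted.
        """
        if a < b:
            a, b = b, a
        seg = self.segments
        keep = []
        for _, row in seg.iterrows():
            if row["chromosome"] != chromosome or row["end"] < start or row["start"] > end:
                keep.append(row)
                continue
            if row["start"] < start:
                left = row.copy()
                left["end"] = start - 1
                keep.append(left)
            if row["end"] > end:
                right = row.copy()
                right["start"] = end + 1
                keep.append(right)
        keep.append(
            pd.Series({"chromosome": chromosome, "start": start, "end": end, "a": a, "b": b})
        )
        table = pd.DataFrame(keep).reset_index(drop=True)
        return SegmentProfile(self.sample, table)


def profiles_to_table(profiles: list[SegmentProfile]) -> pd.DataFrame:
    """Stack profiles into a single sample-keyed segment table."""
    frames = []
    for p in profiles:
        t = p.segments.copy()
        t.insert(0, "sample", p.sample)
        frames.append(t)
    if not frames:
        return pd.DataFrame(columns=["sample", *SEGMENT_COLUMNS])
    return pd.concat(frames, ignore_index=True)


def table_to_profiles(table: pd.DataFrame) -> list[SegmentProfile]:
    return [
        SegmentProfile(str(sample), grp.drop(columns="sample").reset_index(drop=True))
        for sample, grp in table.groupby("sample", sort=True)
    ]
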