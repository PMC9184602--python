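"""Genomic scar scores: LOH, TAI, LST and their sum (HRDsum).

The three scores count footprints that homologous-recombination-deficient
tumors leave in allele-specific copy-number profiles:

* LOH — maximal runs with minor copy number B = 0 longer than 15 Mb that
  do not span a whole chromosome;
* TAI (telomeric allelic imbalance) — maximal runs of allelic imbalance
  (A != B) anchored at a chromosome end, not crossing the centromere and
  not spanning the whole chromosome;
* LST (large-scale state transitions) — junctions between adjacent
  copy-number states of at least 10 Mb each (after removal of fragments
  shorter than 3 Mb), counted per chromosome arm.

HRDsum = LOH + TAI + LST; a tumor is HRD-positive at HRDsum >= cutpoint
(default 42). All scores are computed on maximal *runs* of equal-state
segments, so they do not depend on how a segmentation algorithm happens
to fragment an event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .config import PipelineConfig
from .genome import GenomeBuild
from .io_errors import ValidationError
from .segments import SegmentProfile

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScarScores:
    sample: str
    loh: int
    tai: int
    lst: int

    @property
    def hrdsum(self) -> int:
        return self.loh + self.tai + self.lst

    def hrd_positive(self, cutpoint: float = 42.0) -> bool:
        return self.hrdsum >= cutpoint


def preprocess_segments(profile: SegmentProfile, build: GenomeBuild) -> SegmentProfile:
    """Sort and merge abutting equal-state segments; validate bounds.

    Idempotent. Segments beyond the chromosome length (or on chromosomes
    absent from the build) raise a validation error.
    """
    seg = profile.segments
    for chrom, grp in seg.groupby("chromosome", sort=False):
        if chrom not in build:
            raise ValidationError(f"profile {profile.sample}: unknown chromosome {chrom}")
        if (grp["end"] > build.length(str(chrom))).any() or (grp["start"] < 1).any():
            raise ValidationError(
                f"profile {profile.sample}: segment outside chromosome bounds on {chrom}"
            )
    merged_rows: list[dict] = []
    for chrom, grp in seg.groupby("chromosome", sort=True):
        current = None
        for row in grp.sort_values("start").itertuples(index=False):
            if (
                current is not None
                and row.start == current["end"] + 1
                and row.a == current["a"]
                and row.b == current["b"]
            ):
                current["end"] = row.end
            else:
                if current is not None:
                    merged_rows.append(current)
                current = {
                    "chromosome": chrom,
                    "start": row.start,
                    "end": row.end,
                    "a": row.a,
                    "b": row.b,
                }
        if current is not None:
            merged_rows.append(current)
    return SegmentProfile(profile.sample, pd.DataFrame(merged_rows, columns=seg.columns))


def _runs(grp: pd.DataFrame, mask) -> list[tuple[int, int]]:
    """Maximal runs (start, end) of consecutive abutting flagged segments."""
    runs: list[tuple[int, int]] = []
    run_start = run_end = None
    for row, flag in zip(grp.itertuples(index=False), mask):
        if flag:
            if run_end is not None and row.start == run_end + 1:
                run_end = row.end
            else:
                if run_start is not None:
                    runs.append((run_start, run_end))
                run_start, run_end = row.start, row.end
        else:
            if run_start is not None:
                runs.append((run_start, run_end))
            run_start = run_end = None
    if run_start is not None:
        runs.append((run_start, run_end))
    return runs


def compute_loh(
    profile: SegmentProfile, build: GenomeBuild, config: PipelineConfig | None = None
) -> int:
    """Count LOH runs: B = 0, longer than ``loh_min_length``, sub-chromosomal."""
    config = config or PipelineConfig()
    profile = preprocess_segments(profile, build)
    count = 0
    for chrom, grp in profile.segments.groupby("chromosome", sort=True):
        grp = grp.sort_values("start")
        if config.loh_count_homdel:
            mask = (grp["b"] == 0).to_numpy()
        else:
            mask = ((grp["b"] == 0) & (grp["a"] > 0)).to_numpy()
        chrom_len = build.length(str(chrom))
        for run_start, run_end in _runs(grp, mask):
            length = run_end - run_start + 1
            whole_chromosome = run_start == 1 and run_end == chrom_len
            if length > config.loh_min_length and not whole_chromosome:
                count += 1
                log.debug(
                    "LOH run %s:%d-%d (%.1f Mb) on sample %s",
                    chrom, run_start, run_end, length / 1e6, profile.sample,
                )
    return count


def compute_tai(
    profile: SegmentProfile, build: GenomeBuild, config: PipelineConfig | None = None
) -> int:
    """Count telomeric allelic-imbalance runs.

    A run qualifies when it touches a chromosome end (start = 1 or
    end = chromosome length), does not intersect the centromere interval,
    does not span the whole chromosome, and reaches ``tai_min_length``.
    """
    config = config or PipelineConfig()
    profile = preprocess_segments(profile, build)
    count = 0
    for chrom, grp in profile.segments.groupby("chromosome", sort=True):
        grp = grp.sort_values("start")
        mask = (grp["a"] != grp["b"]).to_numpy()
        chrom_len = build.length(str(chrom))
        cen_start, cen_end = build.centromere(str(chrom))
        for run_start, run_end in _runs(grp, mask):
            length = run_end - run_start + 1
            telomeric = run_start == 1 or run_end == chrom_len
            crosses_centromere = run_start <= cen_end and run_end >= cen_start
            whole_chromosome = run_start == 1 and run_end == chrom_len
            if (
                telomeric
                and not crosses_centromere
                and not whole_chromosome
                and length >= config.tai_min_length
            ):
                count += 1
                log.debug(
                    "TAI run %s:%d-%d (%.1f Mb) on sample %s",
                    chrom, run_start, run_end, length / 1e6, profile.sample,
                )
    return count


def _arm_segments(profile: SegmentProfile, build: GenomeBuild) -> list[list[dict]]:
    """Segments per arm; segments overlapping the centromere are split."""
    arms = []
    for arm in build.arms():
        rows = []
        sub = profile.overlapping(arm.chromosome, arm.start, arm.end)
        for row in sub.itertuples(index=False):
            rows.append(
                {
                    "start": max(int(row.start), arm.start),
                    "end": min(int(row.end), arm.end),
                    "a": int(row.a),
                    "b": int(row.b),
                }
            )
        if rows:
            arms.append(sorted(rows, key=lambda r: r["start"]))
    return arms


def _smooth_arm(rows: list[dict], min_keep: int, merge_gap: int) -> list[dict]:
    """Iteratively drop fragments < ``min_keep`` and re-merge equal states.

    Equal-state neighbours closer than ``merge_gap`` are merged (the gap
    is absorbed). The smallest fragment is removed first; iterated to a
    fixed point.
    """

    def merge(rows: list[dict]) -> list[dict]:
        out: list[dict] = []
        for r in rows:
            if (
                out
                and out[-1]["a"] == r["a"]
                and out[-1]["b"] == r["b"]
                and r["start"] - out[-1]["end"] - 1 <= merge_gap
            ):
                out[-1]["end"] = r["end"]
            else:
                out.append(dict(r))
        return out

    rows = merge(rows)
    while True:
        lengths = [r["end"] - r["start"] + 1 for r in rows]
        small = [i for i, ln in enumerate(lengths) if ln < min_keep]
        if not small:
            return rows
        drop = min(small, key=lambda i: lengths[i])
        rows = merge(rows[:drop] + rows[drop + 1 :])


def compute_lst(
    profile: SegmentProfile, build: GenomeBuild, config: PipelineConfig | None = None
) -> int:
    """Count large-scale state transitions per arm.

    After smoothing (fragments < ``lst_smoothing`` removed, equal flanks
    re-merged to a fixed point), a junction counts when both flanking
    segments are >= ``lst_min_segment``, their states differ and the gap
    between them is <= ``lst_smoothing``.
    """
    config = config or PipelineConfig()
    profile = preprocess_segments(profile, build)
    count = 0
    for rows in _arm_segments(profile, build):
        rows = _smooth_arm(rows, config.lst_smoothing, config.lst_smoothing)
        for left, right in zip(rows, rows[1:]):
            if (left["a"], left["b"]) == (right["a"], right["b"]):
                continue
            gap = right["start"] - left["end"] - 1
            len_left = left["end"] - left["start"] + 1
            len_right = right["end"] - right["start"] + 1
            if (
                gap <= config.lst_smoothing
                and len_left >= config.lst_min_segment
                and len_right >= config.lst_min_segment
            ):
                count += 1
    return count


def compute_scar_scores(
    profile: SegmentProfile, build: GenomeBuild, config: PipelineConfig | None = None
) -> ScarScores:
    """LOH, TAI and LST for one profile (HRDsum is their sum)."""
    config = config or PipelineConfig()
    pre = preprocess_segments(profile, build)
    return ScarScores(
        sample=profile.sample,
        loh=compute_loh(pre, build, config),
        tai=compute_tai(pre, build, config),
        lst=compute_lst(pre, build, config),
    )


def score_profiles(
    profiles: list[SegmentProfile],
    build: GenomeBuild,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Score many profiles into a tidy table."""
    config = config or PipelineConfig()
    rows = []
    for p in profiles:
        s = compute_scar_scores(p, build, config)
        rows.append(
            {
                "sample": s.sample,
                "LOH": s.loh,
                "TAI": s.tai,
                "LST": s.lst,
                "HRDsum": s.hrdsum,
                "HRD_positive": s.hrd_positive(config.hrd_cutpoint),
            }
        )
    return pd.DataFrame(rows)
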