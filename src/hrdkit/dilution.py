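"""In-silico purity dilution at allele-count level.

The influence of tumor purity on HRDsum is emulated without touching
reads: heterozygous-locus allele counts are simulated from a known
segment profile, tumor and matched-normal counts are mixed at a tumor
fraction f (binomial thinning, depth preserved in expectation), integer
allele-specific copy numbers are re-fit by a purity/ploidy grid search,
and the scar scores of the re-fit profile are compared with the
undiluted ones.

For a segment with allele copy numbers (A, B), CN = A + B, in a sample
of purity p the expected B-allele fraction at a heterozygous locus is

    BAF = ((1 - p) + p B) / (2 (1 - p) + p CN)

and the expected relative coverage is (2 (1 - p) + p CN) normalized to
the length-weighted sample average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .genome import GenomeBuild, default_build
from .io_errors import ValidationError
from .scars import compute_scar_scores
from .segments import SegmentProfile

log = logging.getLogger(__name__)


@dataclass
class AlleleCounts:
    """Heterozygous-locus counts plus the segment grid they live on.

    ``loci`` columns: segment_id, chromosome, position, depth, b_count.
    ``segments`` columns: segment_id, chromosome, start, end (the
    segmentation is treated as known).
    """

    loci: pd.DataFrame
    segments: pd.DataFrame

    def __post_init__(self) -> None:
        if ((self.loci["b_count"] < 0) | (self.loci["b_count"] > self.loci["depth"])).any():
            raise ValidationError("b_count must lie in [0, depth]")


def expected_baf(a: int, b: int, purity: float) -> float:
    """Expected B-allele fraction of a (a, b) segment at given purity."""
    cn = a + b
    return ((1 - purity) + purity * b) / (2 * (1 - purity) + purity * cn)


def simulate_allele_counts(
    profile: SegmentProfile,
    purity: float = 1.0,
    depth: int = 100,
    loci_per_segment: int = 150,
    seed=None,
) -> AlleleCounts:
    """Per-locus binomial counts from a profile.

    With ``seed=None`` counts are noiseless (expected values rounded to
    integers); otherwise locus depths are Poisson and B-counts binomial.
    The default locus density (150 heterozygous loci per segment) is
    conservative for array or exome data, where multi-megabase segments
    carry hundreds to thousands of informative SNPs.
    """
    if not (0 < purity <= 1):
        raise ValidationError("purity must be in (0, 1]")
    rng = np.random.default_rng(seed) if seed is not None else None
    seg = profile.segments.reset_index(drop=True)
    nseg = len(seg)
    lengths = (seg["end"] - seg["start"] + 1).to_numpy(dtype=float)
    raw_cov = 2 * (1 - purity) + purity * (seg["a"] + seg["b"]).to_numpy(dtype=float)
    rel_cov = raw_cov / np.average(raw_cov, weights=lengths)
    bafs = np.array(
        [expected_baf(int(a), int(b), purity) for a, b in zip(seg["a"], seg["b"])]
    )

    seg_ids = np.repeat(np.arange(nseg), loci_per_segment)
    positions = np.concatenate(
        [
            np.linspace(s, e, loci_per_segment).astype(int)
            for s, e in zip(seg["start"], seg["end"])
        ]
    )
    target = np.repeat(depth * rel_cov, loci_per_segment)
    baf_per_locus = np.repeat(bafs, loci_per_segment)
    if rng is None:
        depths = np.maximum(np.rint(target).astype(int), 1)
        bs = np.rint(depths * baf_per_locus).astype(int)
    else:
        depths = np.maximum(rng.poisson(target), 1)
        bs = rng.binomial(depths, baf_per_locus)
    loci = pd.DataFrame(
        {
            "segment_id": seg_ids,
            "chromosome": np.repeat(seg["chromosome"].to_numpy(), loci_per_segment),
            "position": positions,
            "depth": depths,
            "b_count": bs,
        }
    )
    seg_table = pd.DataFrame(
        {
            "segment_id": np.arange(nseg),
            "chromosome": seg["chromosome"],
            "start": seg["start"].astype(int),
            "end": seg["end"].astype(int),
        }
    )
    return AlleleCounts(loci, seg_table)


def dilute_counts(
    tumor: AlleleCounts,
    normal: AlleleCounts,
    fraction: float,
    seed=None,
) -> AlleleCounts:
    """Mix tumor and normal reads at tumor fraction ``fraction``.

    Each tumor read is kept with probability f, and normal reads are
    admitted with probability 1 - f, so depth is preserved in
    expectation. With ``seed=None`` the mixing is deterministic
    (expected counts, rounded).
    """
    if not (0 <= fraction <= 1):
        raise ValidationError("fraction must be in [0, 1]")
    t, n = tumor.loci, normal.loci
    if len(t) != len(n) or not (
        (t["chromosome"].to_numpy() == n["chromosome"].to_numpy()).all()
        and (t["position"].to_numpy() == n["position"].to_numpy()).all()
    ):
        raise ValidationError("tumor and normal loci do not match")
    rng = np.random.default_rng(seed) if seed is not None else None
    tb = t["b_count"].to_numpy()
    tr = t["depth"].to_numpy() - tb
    nb = n["b_count"].to_numpy()
    nr = n["depth"].to_numpy() - nb
    if rng is None:
        keep_b = np.rint(fraction * tb).astype(int)
        keep_r = np.rint(fraction * tr).astype(int)
        add_b = np.rint((1 - fraction) * nb).astype(int)
        add_r = np.rint((1 - fraction) * nr).astype(int)
    else:
        keep_b = rng.binomial(tb, fraction)
        keep_r = rng.binomial(tr, fraction)
        add_b = rng.binomial(nb, 1 - fraction)
        add_r = rng.binomial(nr, 1 - fraction)
    b = keep_b + add_b
    depth = np.maximum(b + keep_r + add_r, 1)
    loci = t.copy()
    loci["b_count"] = b
    loci["depth"] = depth
    return AlleleCounts(loci, tumor.segments.copy())


@dataclass(frozen=True)
class CnFit:
    purity: float
    ploidy: float
    segments: pd.DataFrame  # segment_id, chromosome, start, end, a, b
    goodness: float  # length-weighted mean squared distance to integers


def fit_allele_specific_cn(
    counts: AlleleCounts,
    purity_grid: np.ndarray | None = None,
    ploidy_grid: np.ndarray | None = None,
) -> CnFit:
    """Grid-search purity/ploidy fit of integer allele-specific copy numbers.

    For each candidate (p, psi) the observed per-segment BAF and relative
    coverage are inverted to continuous (A, B); the candidate minimizing
    the length-weighted squared distance to non-negative integers wins.
    Exact ties are broken toward higher purity, then ploidy closest to 2
    (the parsimonious near-diploid reading of an ambiguous profile).
    """
    if purity_grid is None:
        purity_grid = np.round(np.arange(0.05, 1.0 + 1e-9, 0.01), 2)
    if ploidy_grid is None:
        ploidy_grid = np.round(np.arange(1.5, 5.0 + 1e-9, 0.05), 2)

    grouped = counts.loci.groupby("segment_id")
    baf = (grouped["b_count"].sum() / grouped["depth"].sum()).to_numpy(dtype=float)
    mean_depth = grouped["depth"].mean()
    seg = counts.segments.set_index("segment_id").loc[mean_depth.index]
    lengths = (seg["end"] - seg["start"] + 1).to_numpy(dtype=float)
    if np.allclose(baf, 0) or len(baf) == 0:
        raise ValidationError("no informative heterozygous loci")
    cov = mean_depth.to_numpy(dtype=float)
    cov = cov / np.average(cov, weights=lengths)
    weights = lengths / lengths.sum()

    p = purity_grid[:, None, None]  # (P, 1, 1)
    psi = ploidy_grid[None, :, None]  # (1, Q, 1)
    d = 2 * (1 - p) + p * psi  # sample-average copy signal
    tot = (cov[None, None, :] * d - 2 * (1 - p)) / p  # continuous CN
    b = (baf[None, None, :] * cov[None, None, :] * d - (1 - p)) / p
    a = tot - b
    ai = np.clip(np.rint(a), 0, None)
    bi = np.clip(np.rint(b), 0, None)
    dist = ((a - ai) ** 2 + (b - bi) ** 2) * weights[None, None, :]
    goodness = dist.sum(axis=2)  # (P, Q)

    best = goodness.min()
    # (A,B) -> (A+k, B+k) with purity p/(1-p) is an exact reparametrization
    # of the same data, so near-minimal candidates are statistically
    # indistinguishable; resolve the degeneracy by parsimony: ploidy
    # closest to diploid, then the higher purity, then the lower ploidy.
    tied = np.argwhere(goodness <= 2 * best + 1e-9)
    order = sorted(
        (tuple(ij) for ij in tied),
        key=lambda ij: (
            abs(ploidy_grid[ij[1]] - 2),
            -purity_grid[ij[0]],
            ploidy_grid[ij[1]],
        ),
    )
    pi, qi = order[0]
    fit_a = ai[pi, qi].astype(int)
    fit_b = bi[pi, qi].astype(int)
    swap = fit_b > fit_a
    fit_a2 = np.where(swap, fit_b, fit_a)
    fit_b2 = np.where(swap, fit_a, fit_b)
    out = seg.reset_index()[["segment_id", "chromosome", "start", "end"]].copy()
    out["a"] = fit_a2
    out["b"] = fit_b2
    return CnFit(
        purity=float(purity_grid[pi]),
        ploidy=float(ploidy_grid[qi]),
        segments=out,
        goodness=float(goodness[pi, qi]),
    )


def fit_to_profile(fit: CnFit, sample: str) -> SegmentProfile:
    return SegmentProfile(
        sample, fit.segments[["chromosome", "start", "end", "a", "b"]].copy()
    )


def dilution_series(
    profile: SegmentProfile,
    fractions=tuple(np.round(np.arange(1.0, 0.0, -0.1), 1)),
    depth: int = 100,
    loci_per_segment: int = 150,
    seed=0,
    purity: float = 1.0,
    build: GenomeBuild | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Scar scores along a tumor-fraction dilution series.

    Returns one row per fraction: the re-fit LOH/TAI/LST/HRDsum and
    HRDsum as a percentage of the undiluted (f = 1) sample.
    """
    build = build or default_build()
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed) if seed is not None else None

    def rng_or_none():
        return rng if rng is not None else None

    tumor = simulate_allele_counts(profile, purity, depth, loci_per_segment, rng_or_none())
    normal_profile = SegmentProfile(
        profile.sample + "_normal",
        profile.segments.assign(a=1, b=1),
    )
    normal = simulate_allele_counts(normal_profile, 1.0, depth, loci_per_segment, rng_or_none())

    rows = []
    undiluted = None
    for f in sorted(fractions, reverse=True):
        mixed = dilute_counts(tumor, normal, float(f), rng_or_none())
        fit = fit_allele_specific_cn(mixed)
        scores = compute_scar_scores(fit_to_profile(fit, profile.sample), build, config)
        hrdsum = scores.hrdsum
        if f == 1.0 or (undiluted is None and not rows):
            undiluted = hrdsum
        pct = 100.0 * hrdsum / undiluted if undiluted else (100.0 if hrdsum == 0 else np.nan)
        rows.append(
            {
                "sample": profile.sample,
                "fraction": float(f),
                "fit_purity": fit.purity,
                "fit_ploidy": fit.ploidy,
                "LOH": scores.loh,
                "TAI": scores.tai,
                "LST": scores.lst,
                "HRDsum": hrdsum,
                "pct_of_undiluted": pct,
            }
        )
    return pd.DataFrame(rows)
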