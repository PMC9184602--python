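"""Synthetic cohorts with planted ground truth.

Everything downstream of real segmentation/variant-calling pipelines can
be exercised on cohorts generated here: segment profiles with planted
scar events, variant tables engineered to produce chosen tiers and hit
types, beta-value tables with chosen methylation status, and per-class
score distributions. The generator records full truth so round-trip
tests can demand exact recovery.

Planted scar events are built from templates that isolate the three
scores: every template flanks its core with 5 Mb buffer segments (kept
by LST smoothing but too short to qualify as LST junction partners), so
a planted LOH run adds no LST junction and a planted telomeric-imbalance
run adds exactly one TAI. Events are separated by >= 12 Mb of diploid
baseline, far above the run-merging scale, so planted counts are
unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genes import BRCA_GENES, gene_coordinates
from .genome import GenomeBuild, default_build
from .io import parse_db_annotations
from .io_errors import ValidationError
from .methylation import INDICATIVE_CPGS
from .segments import SegmentProfile

log = logging.getLogger(__name__)

MB = 1_000_000
MARGIN = 12 * MB  # baseline spacing between events and to arm boundaries
_TAI_WIDTH = 25 * MB
_LOH_WIDTH = 30 * MB
_LST_WIDTH = 20 * MB

#: cohort labels -> (h_class, hit_type, methylation)
COHORT_LABELS = {
    "h1a_ba": ("H1a", "BA", "unmethylated"),
    "h1a_ma": ("H1a", "MA", "unmethylated"),
    "h1b_ba": ("H1b", "BA", "unmethylated"),
    "h1b_ma": ("H1b", "MA", "unmethylated"),
    "h2a": ("H2a", "n/a", "unmethylated"),
    "h2b": ("H2b", "n/a", "unmethylated"),
    "h3": ("H3", "n/a", "unmethylated"),
    "hm": ("H3", "n/a", "strong"),
}

COMBINED_OF_LABEL = {
    "h1a_ba": "H1a, BA/HM",
    "h1a_ma": "H1a, MA",
    "h1b_ba": "H1b, BA",
    "h1b_ma": "H1b, MA",
    "h2a": "H2a",
    "h2b": "H2b",
    "h3": "H3",
    "hm": "H1a, BA/HM",
}

#: per-class HRDsum distribution parameters (mean, sd); loosely echo the
#: ordering seen in tumor cohorts (biallelic BRCA1/2 and hypermethylated
#: tumors well above the 42 cutpoint, unaltered tumors below) but are
#: plain configuration, not claims.
DEFAULT_SCORE_PARAMS = {
    "h1a_ba": (55.0, 12.0),
    "hm": (55.0, 12.0),
    "h1b_ba": (45.0, 12.0),
    "h1a_ma": (30.0, 12.0),
    "h1b_ma": (30.0, 12.0),
    "h2a": (32.0, 12.0),
    "h2b": (30.0, 12.0),
    "h3": (25.0, 10.0),
}

# interior genes only: loci whose +/- 2 Mb splice window would touch a
# telomere (e.g. FANCA on distal 16q) would plant a spurious telomeric
# imbalance, so they stay out of the pool
OTHER_HRR_SIM_GENES = [
    "ATM", "ATR", "BAP1", "BLM", "CHEK2", "PALB2", "MRE11", "NBN",
    # long-list-only genes (absent from the concise 20-gene list)
    "PTEN", "RAD50", "BARD1", "RAD51",
]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# segment profiles with planted scar events
# ---------------------------------------------------------------------------

def _event_blocks(kind: str, lo: int, chrom_len: int, at_q_telomere: bool = False) -> tuple[list, int]:
    """Template blocks [(start, end, a, b), ...] and total width."""
    if kind == "tai":
        if at_q_telomere:
            return (
                [
                    (chrom_len - 25 * MB + 1, chrom_len - 20 * MB, 3, 1),
                    (chrom_len - 20 * MB + 1, chrom_len, 2, 1),
                ],
                _TAI_WIDTH,
            )
        return ([(1, 20 * MB, 2, 1), (20 * MB + 1, 25 * MB, 3, 1)], _TAI_WIDTH)
    if kind == "loh":
        return (
            [
                (lo, lo + 5 * MB - 1, 2, 1),
                (lo + 5 * MB, lo + 25 * MB - 1, 1, 0),
                (lo + 25 * MB, lo + 30 * MB - 1, 2, 1),
            ],
            _LOH_WIDTH,
        )
    if kind == "lst":
        return (
            [(lo, lo + 5 * MB - 1, 3, 3), (lo + 5 * MB, lo + 20 * MB - 1, 2, 2)],
            _LST_WIDTH,
        )
    raise ValueError(kind)


def simulate_profile(
    build: GenomeBuild | None,
    planted: tuple[int, int, int],
    seed=0,
    sample: str = "S1",
    exclude_chromosomes: tuple[str, ...] = (),
) -> tuple[SegmentProfile, dict]:
    """A diploid (1,1) genome with exactly (L, T, S) planted scar events.

    Raises a validation error naming the available capacity when the
    requested counts do not fit on the build.
    """
    build = build or default_build()
    rng = _as_rng(seed)
    n_loh, n_tai, n_lst = planted
    if min(planted) < 0:
        raise ValidationError("planted counts must be non-negative")

    arms = [a for a in build.arms() if a.chromosome not in exclude_chromosomes]
    order = rng.permutation(len(arms))
    arms = [arms[i] for i in order]

    blocks: dict[str, list] = {}
    # telomeric allelic-imbalance events: one per arm telomere
    tai_arms = [a for a in arms if a.length >= _TAI_WIDTH + 2 * MARGIN]
    if n_tai > len(tai_arms):
        raise ValidationError(
            f"cannot plant {n_tai} TAI events: only {len(tai_arms)} arms available"
        )
    tai_used = tai_arms[:n_tai]
    for arm in tai_used:
        at_q = arm.name == "q"
        chrom_len = build.length(arm.chromosome)
        blk, _ = _event_blocks("tai", 0, chrom_len, at_q_telomere=at_q)
        blocks.setdefault(arm.chromosome, []).extend(blk)

    # interior events, greedily left-to-right with jittered spacing
    interior = ["loh"] * n_loh + ["lst"] * n_lst
    rng.shuffle(interior)
    remaining = list(interior)
    for arm in arms:
        if not remaining:
            break
        lo = arm.start + MARGIN
        hi = arm.end - MARGIN
        used = next((a for a in tai_used if a == arm), None)
        if used is not None:
            if arm.name == "p":
                lo = max(lo, arm.start + _TAI_WIDTH + MARGIN)
            else:
                hi = min(hi, arm.end - _TAI_WIDTH - MARGIN)
        cursor = lo
        while remaining:
            kind = remaining[0]
            blk, width = _event_blocks(kind, cursor, build.length(arm.chromosome))
            if cursor + width - 1 > hi:
                break
            blocks.setdefault(arm.chromosome, []).extend(blk)
            remaining.pop(0)
            cursor += width + MARGIN + int(rng.integers(0, 3 * MB))
    if remaining:
        placed = len(interior) - len(remaining)
        raise ValidationError(
            f"cannot plant {len(interior)} interior events on this build: "
            f"capacity exhausted after {placed}"
        )

    rows = []
    for chrom in build.chromosomes:
        chrom_len = build.length(chrom)
        placed = sorted(blocks.get(chrom, []))
        cursor = 1
        for start, end, a, b in placed:
            if start > cursor:
                rows.append((chrom, cursor, start - 1, 1, 1))
            rows.append((chrom, start, end, a, b))
            cursor = end + 1
        if cursor <= chrom_len:
            rows.append((chrom, cursor, chrom_len, 1, 1))
    profile = SegmentProfile(
        sample,
        pd.DataFrame(rows, columns=["chromosome", "start", "end", "a", "b"]),
    )
    truth = {"loh": n_loh, "tai": n_tai, "lst": n_lst}
    return profile, truth


def simulate_random_profile(
    build: GenomeBuild | None = None,
    seed=0,
    sample: str = "R1",
    max_breaks: int = 6,
    max_copy: int = 3,
) -> SegmentProfile:
    """An unconstrained random profile (for invariance/property testing).

    Each chromosome is cut at 0..``max_breaks`` random points and every
    piece gets a random allele-specific state with A >= B, biased toward
    the diploid heterozygous state.
    """
    build = build or default_build()
    rng = _as_rng(seed)
    states = [(a, b) for a in range(max_copy + 1) for b in range(a + 1)]
    weights = np.array([4.0 if s == (1, 1) else 1.0 for s in states])
    weights /= weights.sum()
    rows = []
    for chrom in build.chromosomes:
        chrom_len = build.length(chrom)
        k = int(rng.integers(0, max_breaks + 1))
        cuts = np.sort(rng.integers(2, chrom_len, size=k))
        bounds = [1, *[int(c) for c in np.unique(cuts)], chrom_len + 1]
        for lo, hi in zip(bounds, bounds[1:]):
            if hi <= lo:
                continue
            a, b = states[int(rng.choice(len(states), p=weights))]
            rows.append((chrom, lo, hi - 1, a, b))
    return SegmentProfile(
        sample, pd.DataFrame(rows, columns=["chromosome", "start", "end", "a", "b"])
    )


# ---------------------------------------------------------------------------
# variant tables with engineered tiers and hit types
# ---------------------------------------------------------------------------

@dataclass
class GeneDesign:
    """What the generator must do for one tumor's HRR gene."""

    gene: str
    rows: list[dict] = field(default_factory=list)
    splice: tuple[int, int] | None = None  # locus state forced at the gene
    ba_criterion: int | None = None


def _variant_row(
    sample: str,
    gene: str,
    chrom: str,
    pos: int,
    origin: str,
    classification: str,
    raw_vaf: float,
    db: str,
    rng: np.random.Generator,
    depth: int,
) -> dict:
    alt = int(rng.binomial(depth, raw_vaf))
    alt = min(max(alt, 1), depth)  # keep the record informative
    return {
        "sample": sample,
        "gene": gene,
        "chromosome": chrom,
        "position": pos,
        "ref": "A",
        "alt": "T",
        "variant_classification": classification,
        "origin": origin,
        "t_alt_count": alt,
        "t_ref_count": depth - alt,
        "db_annotations": db,
    }


def _deleterious_somatic(kind: int) -> tuple[str, str]:
    """(classification, db) alternatives that land in the deleterious tiers."""
    if kind == 0:
        return "Missense_Mutation", "clinvar:pathogenic"
    return "Frame_Shift_Del", ""


def design_gene_events(
    sample: str,
    label: str,
    gene: str,
    coords: tuple[str, int, int],
    purity: float,
    rng: np.random.Generator,
    depth: int = 600,
    ba_criterion: int | None = None,
) -> GeneDesign:
    """Variant rows plus the locus state that realize a target class/hit type.

    For biallelic targets one of the five criteria is chosen (or given)
    and the VAF targets are placed well clear of the alpha/beta
    thresholds so binomial read-count noise cannot flip the call.
    """
    chrom, gstart, gend = coords
    pos = int(rng.integers(gstart, gend + 1))
    design = GeneDesign(gene=gene)
    h_class, hit_type, _ = COHORT_LABELS[label]

    def row(origin, classification, corrected_vaf, db):
        raw = corrected_vaf * purity if origin == "somatic" else corrected_vaf
        return _variant_row(
            sample, gene, chrom, pos, origin, classification, raw, db, rng, depth
        )

    if h_class in ("H1a", "H1b") and hit_type == "BA":
        crit = ba_criterion if ba_criterion is not None else int(rng.integers(1, 6))
        design.ba_criterion = crit
        if crit == 1:  # homozygous deletion
            design.splice = (0, 0)
        elif crit == 2:  # LOH + germline
            design.splice = (1, 0)
            design.rows.append(row("germline", "Missense_Mutation", 0.5, "clinvar:pathogenic"))
        elif crit == 3:  # LOH + somatic with VAF >= alpha
            design.splice = (2, 0)  # alpha = 0.5
            cls, db = _deleterious_somatic(int(rng.integers(0, 2)))
            design.rows.append(row("somatic", cls, 0.85, db))
        elif crit == 4:  # germline + somatic with VAF >= beta
            design.splice = None  # baseline (1,1): beta = 0.25
            design.rows.append(row("germline", "Missense_Mutation", 0.5, "clinvar:pathogenic"))
            cls, db = _deleterious_somatic(int(rng.integers(0, 2)))
            design.rows.append(row("somatic", cls, 0.55, db))
        else:  # two somatic mutations
            design.splice = None  # baseline (1,1): alpha = beta = 0.25
            for target in (0.62, 0.45):
                cls, db = _deleterious_somatic(int(rng.integers(0, 2)))
                design.rows.append(row("somatic", cls, target, db))
    elif h_class in ("H1a", "H1b") and hit_type == "MA":
        if rng.integers(0, 2) == 0:
            design.rows.append(row("germline", "Missense_Mutation", 0.5, "clinvar:pathogenic"))
        else:
            # single somatic hit at a heterozygous diploid locus: never BA
            cls, db = _deleterious_somatic(int(rng.integers(0, 2)))
            design.rows.append(row("somatic", cls, 0.40, db))
    elif h_class in ("H2a", "H2b"):
        design.rows.append(row("somatic", "Missense_Mutation", 0.30, ""))
    else:  # H3 (possibly with an irrelevant polymorphism)
        if rng.integers(0, 2) == 0:
            design.rows.append(row("somatic", "Silent", 0.30, ""))
    return design


def finalize_variant_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble generator rows into the reader's in-memory form."""
    from .io import VARIANT_COLUMNS

    table = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    alt = table["t_alt_count"].astype(float)
    ref = table["t_ref_count"].astype(float)
    total = alt + ref
    table["vaf"] = np.where(total > 0, alt / total, np.nan)
    table["db_assessments"] = table["db_annotations"].map(parse_db_annotations)
    return table


# ---------------------------------------------------------------------------
# methylation tables
# ---------------------------------------------------------------------------

def simulate_methylation(
    statuses: pd.Series,
    seed=0,
    probes: tuple[str, ...] = INDICATIVE_CPGS,
) -> pd.DataFrame:
    """Beta matrix whose per-sample calls equal the target statuses."""
    rng = _as_rng(seed)
    data = {}
    for sample, status in statuses.items():
        betas = rng.uniform(0.01, 0.15, size=len(probes))
        hot = int(rng.integers(0, len(probes)))
        if status == "strong":
            betas[hot] = rng.uniform(0.65, 0.95)
        elif status == "moderate":
            betas[hot] = rng.uniform(0.25, 0.55)
        elif status != "unmethylated":
            raise ValidationError(f"unknown methylation target {status!r}")
        data[sample] = betas
    return pd.DataFrame(data, index=list(probes))


def simulate_methylation_with_expression(
    n_samples: int,
    seed=0,
    n_decoys: int = 4,
) -> tuple[pd.DataFrame, pd.Series, set[str]]:
    """Probe panel for CpG-selection tests.

    The four indicative probes are strongly anticorrelated with a
    simulated expression track; decoy probes are independent of it.
    """
    rng = _as_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    expr = pd.Series(rng.uniform(0.0, 1.0, n_samples), index=samples, name="expression")
    rows = {}
    for probe in INDICATIVE_CPGS:
        noise = rng.normal(0, 0.03, n_samples)
        rows[probe] = np.clip(0.9 - 0.8 * expr.to_numpy() + noise, 0, 1)
    for i in range(n_decoys):
        rows[f"cg_decoy_{i:02d}"] = rng.uniform(0, 1, n_samples)
    betas = pd.DataFrame(rows).T
    betas.columns = samples
    return betas, expr, set(INDICATIVE_CPGS)


# ---------------------------------------------------------------------------
# whole cohorts
# ---------------------------------------------------------------------------

def _allocate_classes(n: int, mixture: dict[str, float], rng) -> list[str]:
    """Deterministic largest-remainder allocation, then a seeded shuffle."""
    if abs(sum(mixture.values()) - 1) > 1e-9:
        raise ValidationError("class mixture must sum to 1")
    for label in mixture:
        if label not in COHORT_LABELS:
            raise ValidationError(f"unknown cohort label {label!r}")
    base = {k: int(np.floor(v * n)) for k, v in mixture.items()}
    short = n - sum(base.values())
    remainders = sorted(
        mixture, key=lambda k: (mixture[k] * n - base[k]), reverse=True
    )
    for k in remainders[:short]:
        base[k] += 1
    labels = [k for k, c in base.items() for _ in range(c)]
    rng.shuffle(labels)
    return labels


def simulate_cohort(
    n: int,
    class_mixture: dict[str, float],
    seed=0,
    build: GenomeBuild | None = None,
    score_params: dict[str, tuple[float, float]] | None = None,
    depth: int = 600,
    max_planted: int = 2,
) -> dict:
    """Generate a joint cohort: segments, variants, methylation, purity, scores.

    Returns a dict with keys ``profiles`` (list of SegmentProfile),
    ``variants`` (DataFrame), ``methylation`` (beta matrix), ``purity``
    (Series), ``scores`` (per-sample emulated HRDsum draws) and ``truth``
    (DataFrame with the planted labels).
    """
    build = build or default_build()
    rng = _as_rng(seed)
    score_params = {**DEFAULT_SCORE_PARAMS, **(score_params or {})}
    coords_table = gene_coordinates()
    coords = {
        r["gene"]: (str(r["chromosome"]), int(r["start"]), int(r["end"]))
        for _, r in coords_table.iterrows()
    }
    labels = _allocate_classes(n, class_mixture, rng)

    profiles, var_rows, truth_rows = [], [], []
    statuses, purities, scores = {}, {}, {}
    for i, label in enumerate(labels):
        sample = f"T{i:04d}"
        h_class, hit_type, meth = COHORT_LABELS[label]
        if meth == "strong":
            meth = str(rng.choice(["strong", "moderate"]))
        purity = float(np.round(rng.uniform(0.6, 1.0), 3))
        if h_class in ("H1a", "H2a"):
            gene = str(rng.choice(["BRCA1", "BRCA2"]))
        elif h_class in ("H1b", "H2b"):
            gene = str(rng.choice(OTHER_HRR_SIM_GENES))
        else:
            gene = str(rng.choice(OTHER_HRR_SIM_GENES))
        design = design_gene_events(
            sample, label, gene, coords[gene], purity, rng, depth
        )
        planted = tuple(int(x) for x in rng.integers(0, max_planted + 1, size=3))
        profile, _ = simulate_profile(
            build,
            planted,
            rng,
            sample=sample,
            exclude_chromosomes=(coords[gene][0],),
        )
        if design.splice is not None:
            chrom, gstart, gend = coords[gene]
            profile = profile.splice(
                chrom,
                max(1, gstart - 2 * MB),
                min(build.length(chrom), gend + 2 * MB),
                *design.splice,
            )
        profiles.append(profile)
        var_rows.extend(design.rows)
        statuses[sample] = meth
        purities[sample] = purity
        mean, sd = score_params[label]
        scores[sample] = float(rng.normal(mean, sd))
        truth_rows.append(
            {
                "sample": sample,
                "label": label,
                "h_class": h_class,
                "hit_type": hit_type,
                "ba_criterion": design.ba_criterion,
                "methylation": meth,
                "combined_class": COMBINED_OF_LABEL[label],
                "gene": gene,
                "purity": purity,
                "planted_loh": planted[0],
                "planted_tai": planted[1],
                "planted_lst": planted[2],
            }
        )

    status_series = pd.Series(statuses)
    return {
        "profiles": profiles,
        "variants": finalize_variant_table(var_rows),
        "methylation": simulate_methylation(status_series, rng),
        "purity": pd.Series(purities, name="purity"),
        "scores": pd.DataFrame(
            {
                "sample": list(scores),
                "score": list(scores.values()),
                "label": labels,
            }
        ),
        "truth": pd.DataFrame(truth_rows),
    }
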