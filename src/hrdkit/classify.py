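"""Tumor classification: H-classes, hit types, combined classes.

Tumors are assigned to one of five classes by their HRR-gene mutation
status, in strict priority order:

* H1a — (likely) deleterious alteration in BRCA1/2 (incl. homozygous
  deletion);
* H1b — otherwise, (likely) deleterious alteration in another HRR gene;
* H2a — otherwise, VUS in BRCA1/2;
* H2b — otherwise, VUS in another HRR gene;
* H3 — wildtype or alterations with retained function only.

For reporting, H1a/H1b split by allelic hit type (BA/MA), and BRCA1
promoter-hypermethylated tumors join the biallelic BRCA1/2 class to form
the combined class "H1a, BA/HM".
"""

from __future__ import annotations

import logging

import pandas as pd

from .config import PipelineConfig
from .genes import BRCA_GENES, GeneList
from .genome import GenomeBuild
from .hit_type import HitEvent, classify_hit_type
from .io_errors import ValidationError
from .methylation import INDICATIVE_CPGS, call_methylation_matrix
from .scars import score_profiles
from .segments import SegmentProfile
from .variants import (
    GeneAlteration,
    Tier,
    classify_variant_table,
    compute_tmb_tib,
    summarize_gene_alterations,
)

log = logging.getLogger(__name__)

H_CLASSES = ("H1a", "H1b", "H2a", "H2b", "H3")


def assign_h_class(alterations: dict[str, GeneAlteration]) -> str:
    """H-class of one sample from its per-gene alterations (gene -> events)."""

    def worst(genes) -> Tier | None:
        tiers = [alterations[g].worst_tier for g in genes if g in alterations]
        return max(tiers) if tiers else None

    brca = worst(BRCA_GENES)
    other = worst(set(alterations) - BRCA_GENES)
    if brca is not None and brca.is_deleterious:
        return "H1a"
    if other is not None and other.is_deleterious:
        return "H1b"
    if brca == Tier.VUS:
        return "H2a"
    if other == Tier.VUS:
        return "H2b"
    return "H3"


def assign_combined_class(
    h_class: str,
    hit_type: str | None,
    methylation: str,
    config: PipelineConfig | None = None,
) -> str:
    """Reporting class combining H-class, hit type and methylation.

    Hypermethylated tumors (strong, plus moderate unless configured off)
    are pooled with the biallelic deleterious BRCA1/2 tumors.
    """
    config = config or PipelineConfig()
    hyper = {"strong", "moderate"} if config.include_moderate_hm_in_combined else {"strong"}
    if methylation in hyper:
        return "H1a, BA/HM"
    if h_class in ("H1a", "H1b"):
        if hit_type not in ("BA", "MA"):
            raise ValidationError(f"{h_class} tumor without a hit type")
        if h_class == "H1a" and hit_type == "BA":
            return "H1a, BA/HM"
        return f"{h_class}, {hit_type}"
    return h_class


def _hit_type_for_sample(
    h_class: str,
    alterations: dict[str, GeneAlteration],
    profile: SegmentProfile | None,
    purity: float,
) -> tuple[str | None, int | None]:
    """BA/MA for the class-defining genes; BA wins if any gene is BA."""
    if h_class not in ("H1a", "H1b"):
        return None, None
    if h_class == "H1a":
        genes = [g for g in alterations if g in BRCA_GENES]
    else:
        genes = [g for g in alterations if g not in BRCA_GENES]
    genes = [g for g in genes if alterations[g].worst_tier.is_deleterious]
    calls = []
    for gene in genes:
        alt = alterations[gene]
        events = []
        if len(alt.variants):
            deleterious = alt.variants[alt.variants["tier"] >= Tier.LIKELY_DELETERIOUS]
            for row in deleterious.itertuples(index=False):
                locus = None
                if profile is not None:
                    locus = profile.locus_state(str(row.chromosome), int(row.position))
                vaf = None if pd.isna(row.vaf) else float(row.vaf)
                events.append(HitEvent(origin=row.origin, vaf=vaf, locus=locus))
        loci = [e.locus for e in events if e.locus is not None]
        gene_locus = loci[0] if loci else None
        calls.append(
            classify_hit_type(
                events,
                locus=gene_locus,
                purity=purity,
                homozygous_deletion=alt.homozygous_deletion,
            )
        )
    if not calls:
        return None, None
    ba = [c for c in calls if c.hit_type == "BA"]
    if ba:
        return "BA", ba[0].criterion
    return "MA", None


def classify_cohort(
    profiles: list[SegmentProfile],
    variants: pd.DataFrame,
    methylation: pd.DataFrame | None,
    purity: pd.Series | None,
    build: GenomeBuild,
    gene_list: GeneList,
    config: PipelineConfig | None = None,
    cancer_types: pd.Series | None = None,
) -> pd.DataFrame:
    """Run the full per-tumor classification.

    Returns one row per sample: h_class, hit_type, criterion,
    methylation, combined_class, scar scores, TMB/TIB, purity.
    """
    config = config or PipelineConfig()
    profile_map = {p.sample: p for p in profiles}
    classified = classify_variant_table(variants) if len(variants) else variants
    alterations = summarize_gene_alterations(classified, profile_map, gene_list)
    by_sample: dict[str, dict[str, GeneAlteration]] = {}
    for (sample, gene), alt in alterations.items():
        by_sample.setdefault(sample, {})[gene] = alt

    meth_calls = (
        call_methylation_matrix(methylation, INDICATIVE_CPGS, config)
        if methylation is not None
        else pd.Series(dtype=object)
    )
    scores = score_profiles(profiles, build, config).set_index("sample")

    samples = sorted(
        set(profile_map)
        | set(by_sample)
        | (set(meth_calls.index) if len(meth_calls) else set())
    )
    rows = []
    for sample in samples:
        alts = by_sample.get(sample, {})
        h_class = assign_h_class(alts)
        if purity is not None and sample in purity.index:
            sample_purity = float(purity[sample])
        else:
            if h_class in ("H1a", "H1b"):
                log.warning("no purity for sample %s; assuming 1.0", sample)
            sample_purity = 1.0
        hit, criterion = _hit_type_for_sample(
            h_class, alts, profile_map.get(sample), sample_purity
        )
        meth = str(meth_calls.get(sample, "unevaluable")) if len(meth_calls) else "unevaluable"
        combined = assign_combined_class(h_class, hit, meth, config)
        sample_variants = (
            classified[classified["sample"] == sample] if len(classified) else classified
        )
        tmb, tib = compute_tmb_tib(sample_variants) if len(variants) else (0, 0)
        row = {
            "sample": sample,
            "h_class": h_class,
            "hit_type": hit if hit is not None else "n/a",
            "ba_criterion": criterion,
            "methylation": meth,
            "combined_class": combined,
            "TMB": tmb,
            "TIB": tib,
            "purity": sample_purity,
        }
        if sample in scores.index:
            for col in ("LOH", "TAI", "LST", "HRDsum", "HRD_positive"):
                row[col] = scores.at[sample, col]
        if cancer_types is not None and sample in cancer_types.index:
            row["cancer_type"] = cancer_types[sample]
        rows.append(row)
    return pd.DataFrame(rows)
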