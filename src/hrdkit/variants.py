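"""Variant tier classification, homozygous deletions, TMB/TIB.

Every germline or somatic HRR-gene variant receives one of five tiers:
deleterious > likely_deleterious > VUS > likely_polymorphism >
polymorphism. Database assessments (pre-joined offline into the variant
table) take precedence; variants absent from every database fall back to
a mutation-type rule: frameshift/nonsense/splice-site are likely
deleterious, intronic/synonymous are polymorphisms, everything else is a
VUS. Homozygous deletions (both allele copy numbers zero over a gene)
are deleterious by definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum

import pandas as pd

from .genes import BRCA_GENES, GeneList
from .io_errors import ValidationError
from .segments import SegmentProfile

log = logging.getLogger(__name__)


class Tier(IntEnum):
    """Five-tier variant classification; higher = more deleterious."""

    POLYMORPHISM = 0
    LIKELY_POLYMORPHISM = 1
    VUS = 2
    LIKELY_DELETERIOUS = 3
    DELETERIOUS = 4

    @property
    def label(self) -> str:
        return self.name.lower()

    @property
    def is_deleterious(self) -> bool:
        return self >= Tier.LIKELY_DELETERIOUS


#: database assessment -> tier
ASSESSMENT_TIER = {
    "pathogenic": Tier.DELETERIOUS,
    "likely_pathogenic": Tier.LIKELY_DELETERIOUS,
    "uncertain_significance": Tier.VUS,
    "likely_benign": Tier.LIKELY_POLYMORPHISM,
    "benign": Tier.POLYMORPHISM,
}

#: MAF Variant_Classification -> fallback tier for database-unlisted variants
MAF_FALLBACK_TIER = {
    "Frame_Shift_Del": Tier.LIKELY_DELETERIOUS,
    "Frame_Shift_Ins": Tier.LIKELY_DELETERIOUS,
    "Nonsense_Mutation": Tier.LIKELY_DELETERIOUS,
    "Splice_Site": Tier.LIKELY_DELETERIOUS,
    "Silent": Tier.POLYMORPHISM,
    "Intron": Tier.POLYMORPHISM,
    "Missense_Mutation": Tier.VUS,
    "In_Frame_Del": Tier.VUS,
    "In_Frame_Ins": Tier.VUS,
    "Nonstop_Mutation": Tier.VUS,
    "Translation_Start_Site": Tier.VUS,
    "Splice_Region": Tier.VUS,
    "5'UTR": Tier.VUS,
    "3'UTR": Tier.VUS,
    "5'Flank": Tier.VUS,
    "3'Flank": Tier.VUS,
    "RNA": Tier.VUS,
}

MISSENSE_TYPES = {"Missense_Mutation"}
INDEL_TYPES = {"Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins"}


def classify_variant(
    mutation_type: str,
    origin: str,
    db_assessments: list[tuple[str, str]] | None,
) -> Tier:
    """Tier one variant.

    Germline: the first listed database source decides. Somatic: a
    unanimous database verdict decides; conflicting assessments yield
    VUS. Database-unlisted variants fall back to the mutation-type rule.
    """
    db_assessments = db_assessments or []
    if db_assessments:
        tiers = [ASSESSMENT_TIER[a] for _, a in db_assessments]
        if origin == "germline":
            tier = tiers[0]
            log.debug("germline db rule: %s -> %s", db_assessments[0], tier.label)
            return tier
        if len(set(tiers)) == 1:
            log.debug("somatic unanimous db rule -> %s", tiers[0].label)
            return tiers[0]
        log.debug("somatic conflicting db assessments %s -> vus", db_assessments)
        return Tier.VUS
    if mutation_type not in MAF_FALLBACK_TIER:
        raise ValidationError(f"unknown mutation type token {mutation_type!r}")
    tier = MAF_FALLBACK_TIER[mutation_type]
    log.debug("fallback type rule: %s -> %s", mutation_type, tier.label)
    return tier


def classify_variant_table(variants: pd.DataFrame) -> pd.DataFrame:
    """Add a ``tier`` column (Tier enum) to a variant table."""
    out = variants.copy()
    out["tier"] = [
        classify_variant(row.variant_classification, row.origin, row.db_assessments)
        for row in out.itertuples(index=False)
    ]
    return out


@dataclass
class GeneAlteration:
    """All events of one gene in one sample."""

    sample: str
    gene: str
    variants: pd.DataFrame  # classified variant rows (may be empty)
    homozygous_deletion: bool = False

    @property
    def worst_tier(self) -> Tier:
        tiers = list(self.variants["tier"]) if len(self.variants) else []
        if self.homozygous_deletion:
            tiers.append(Tier.DELETERIOUS)
        if not tiers:
            raise ValidationError(f"{self.sample}/{self.gene}: no events")
        return Tier(max(tiers))  # pandas stores IntEnum columns as plain ints


def call_homozygous_deletions(
    profile: SegmentProfile,
    genes: GeneList,
    include_brca: bool = True,
) -> set[str]:
    """Genes whose interval overlaps any (0, 0) segment in the profile.

    Any overlap suffices. Genes without packaged coordinates are skipped
    with a warning.
    """
    symbols = set(genes.symbols) | (set(BRCA_GENES) if include_brca else set())
    hits: set[str] = set()
    seg = profile.segments
    homdel = seg[(seg["a"] == 0) & (seg["b"] == 0)]
    if len(homdel) == 0:
        return hits
    for gene in sorted(symbols):
        coords = genes.coordinates(gene)
        if coords is None:
            log.debug("no coordinates for gene %s; skipping homozygous-deletion call", gene)
            continue
        chrom, start, end = coords
        overlap = homdel[
            (homdel["chromosome"] == chrom)
            & (homdel["start"] <= end)
            & (homdel["end"] >= start)
        ]
        if len(overlap):
            hits.add(gene)
            log.debug("homozygous deletion of %s in %s", gene, profile.sample)
    return hits


def compute_tmb_tib(variants: pd.DataFrame) -> tuple[int, int]:
    """(TMB, TIB) for one sample's somatic records.

    TMB is the raw missense count; TIB the raw small-indel count.
    """
    somatic = variants[variants["origin"] == "somatic"] if len(variants) else variants
    if len(somatic) == 0:
        return 0, 0
    tmb = int(somatic["variant_classification"].isin(MISSENSE_TYPES).sum())
    tib = int(somatic["variant_classification"].isin(INDEL_TYPES).sum())
    return tmb, tib


def summarize_gene_alterations(
    variants: pd.DataFrame,
    profiles: dict[str, SegmentProfile] | None,
    genes: GeneList,
) -> dict[tuple[str, str], GeneAlteration]:
    """Group classified variants and homozygous deletions per (sample, gene).

    Only BRCA1/2 and genes on the supplied list are considered.
    """
    relevant = set(genes.symbols) | set(BRCA_GENES)
    out: dict[tuple[str, str], GeneAlteration] = {}
    if len(variants):
        if "tier" not in variants.columns:
            variants = classify_variant_table(variants)
        for (sample, gene), grp in variants.groupby(["sample", "gene"], sort=True):
            if gene not in relevant:
                continue
            out[(str(sample), str(gene))] = GeneAlteration(
                str(sample), str(gene), grp.reset_index(drop=True)
            )
    if profiles:
        for sample, profile in profiles.items():
            for gene in call_homozygous_deletions(profile, genes):
                key = (sample, gene)
                if key in out:
                    out[key].homozygous_deletion = True
                else:
                    out[key] = GeneAlteration(
                        sample, gene, variants.iloc[0:0] if len(variants) else pd.DataFrame(),
                        homozygous_deletion=True,
                    )
    return out
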