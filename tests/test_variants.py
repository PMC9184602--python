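"""Five-tier variant classification, homozygous deletions, TMB/TIB."""

import pandas as pd
import pytest

from hrdkit.genes import load_gene_list
from hrdkit.io_errors import ValidationError
from hrdkit.variants import (
    GeneAlteration,
    Tier,
    call_homozygous_deletions,
    classify_variant,
    compute_tmb_tib,
    summarize_gene_alterations,
)

from conftest import make_profile

MB = 1_000_000


class TestClassifyVariant:
    def test_germline_pathogenic_is_deleterious(self):
        t = classify_variant("Missense_Mutation", "germline", [("huang", "pathogenic")])
        assert t == Tier.DELETERIOUS

    def test_germline_likely_pathogenic(self):
        t = classify_variant("Missense_Mutation", "germline", [("huang", "likely_pathogenic")])
        assert t == Tier.LIKELY_DELETERIOUS

    def test_unlisted_frameshift_likely_deleterious(self):
        assert classify_variant("Frame_Shift_Del", "somatic", []) == Tier.LIKELY_DELETERIOUS

    @pytest.mark.parametrize("mt", ["Nonsense_Mutation", "Splice_Site", "Frame_Shift_Ins"])
    def test_truncating_types(self, mt):
        assert classify_variant(mt, "somatic", []) == Tier.LIKELY_DELETERIOUS

    def test_conflicting_databases_vus(self):
        t = classify_variant(
            "Missense_Mutation",
            "somatic",
            [("clinvar", "pathogenic"), ("lovd", "benign")],
        )
        assert t == Tier.VUS

    def test_unanimous_somatic_databases(self):
        t = classify_variant(
            "Missense_Mutation",
            "somatic",
            [("clinvar", "pathogenic"), ("enigma", "pathogenic")],
        )
        assert t == Tier.DELETERIOUS

    @pytest.mark.parametrize("mt", ["Silent", "Intron"])
    def test_unlisted_silent_intron_polymorphism(self, mt):
        assert classify_variant(mt, "somatic", []) == Tier.POLYMORPHISM

    def test_unlisted_missense_vus(self):
        assert classify_variant("Missense_Mutation", "somatic", []) == Tier.VUS

    def test_unknown_token_raises(self):
        with pytest.raises(ValidationError, match="unknown mutation type"):
            classify_variant("Weird_Thing", "somatic", [])

    def test_order_independence_of_conflict(self):
        a = classify_variant("Silent", "somatic", [("x", "pathogenic"), ("y", "benign")])
        b = classify_variant("Silent", "somatic", [("y", "benign"), ("x", "pathogenic")])
        assert a == b == Tier.VUS


class TestHomozygousDeletions:
    def test_gene_inside_homdel(self):
        genes = load_gene_list("short")
        # ATM: chr11 108222484-108369102
        p = make_profile(
            [
                ("chr11", 1, 108 * MB, 1, 1),
                ("chr11", 108 * MB + 1, 109 * MB, 0, 0),
                ("chr11", 109 * MB + 1, 135086622, 1, 1),
            ]
        )
        assert call_homozygous_deletions(p, genes) == {"ATM"}

    def test_single_retained_allele_no_call(self):
        genes = load_gene_list("short")
        p = make_profile([("chr11", 1, 135086622, 1, 0)])
        assert call_homozygous_deletions(p, genes) == set()

    def test_breakpoint_overlap_suffices(self):
        genes = load_gene_list("short")
        # homdel ends inside ATM
        p = make_profile(
            [
                ("chr11", 1, 108_300_000, 0, 0),
                ("chr11", 108_300_001, 135086622, 1, 1),
            ]
        )
        assert "ATM" in call_homozygous_deletions(p, genes)

    def test_brca_included(self):
        genes = load_gene_list("short")
        p = make_profile(
            [
                ("chr17", 1, 43 * MB, 1, 1),
                ("chr17", 43 * MB + 1, 44 * MB, 0, 0),
                ("chr17", 44 * MB + 1, 83257441, 1, 1),
            ]
        )
        assert "BRCA1" in call_homozygous_deletions(p, genes)


def _som(mt, n=1):
    return [
        {"variant_classification": mt, "origin": "somatic", "gene": "X", "sample": "S"}
        for _ in range(n)
    ]


class TestTmbTib:
    def test_counts(self):
        rows = _som("Missense_Mutation", 5) + _som("Frame_Shift_Del", 2) + _som("Silent", 1)
        tmb, tib = compute_tmb_tib(pd.DataFrame(rows))
        assert (tmb, tib) == (5, 2)

    def test_empty(self):
        assert compute_tmb_tib(pd.DataFrame()) == (0, 0)

    def test_inframe_counts_as_indel(self):
        rows = _som("In_Frame_Del", 3) + _som("Frame_Shift_Ins", 1)
        tmb, tib = compute_tmb_tib(pd.DataFrame(rows))
        assert (tmb, tib) == (0, 4)

    def test_germline_excluded(self):
        rows = pd.DataFrame(
            [
                {"variant_classification": "Missense_Mutation", "origin": "germline"},
                {"variant_classification": "Missense_Mutation", "origin": "somatic"},
            ]
        )
        assert compute_tmb_tib(rows) == (1, 0)

    def test_shuffle_invariance(self):
        rows = pd.DataFrame(
            _som("Missense_Mutation", 4) + _som("In_Frame_Ins", 2) + _som("Intron", 3)
        )
        shuffled = rows.sample(frac=1, random_state=5)
        assert compute_tmb_tib(rows) == compute_tmb_tib(shuffled)


class TestGeneAlterations:
    def _alt(self, tiers, homdel=False):
        df = pd.DataFrame({"tier": tiers})
        return GeneAlteration("S", "G", df, homozygous_deletion=homdel)

    def test_worst_tier_ordering(self):
        assert self._alt([Tier.DELETERIOUS, Tier.VUS]).worst_tier == Tier.DELETERIOUS
        assert self._alt([Tier.POLYMORPHISM]).worst_tier == Tier.POLYMORPHISM

    def test_homdel_only_is_deleterious(self):
        alt = GeneAlteration("S", "G", pd.DataFrame(), homozygous_deletion=True)
        assert alt.worst_tier == Tier.DELETERIOUS

    def test_no_events_raises(self):
        with pytest.raises(ValidationError):
            GeneAlteration("S", "G", pd.DataFrame()).worst_tier

    def test_summarize_filters_to_gene_lists(self):
        genes = load_gene_list("short")
        variants = pd.DataFrame(
            [
                {"sample": "S", "gene": "ATM", "variant_classification": "Silent",
                 "origin": "somatic", "db_assessments": [], "vaf": 0.1},
                {"sample": "S", "gene": "NOT_A_GENE", "variant_classification": "Silent",
                 "origin": "somatic", "db_assessments": [], "vaf": 0.1},
            ]
        )
        out = summarize_gene_alterations(variants, None, genes)
        assert set(out) == {("S", "ATM")}
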