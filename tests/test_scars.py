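"""Scar-score rules on hand-constructed profiles, cross-checked against
naive brute-force run enumerators."""

import pandas as pd
import pytest

from hrdkit.config import PipelineConfig
from hrdkit.io_errors import ValidationError
from hrdkit.scars import (
    compute_loh,
    compute_lst,
    compute_scar_scores,
    compute_tai,
    preprocess_segments,
)
from hrdkit.simulate import simulate_random_profile

from conftest import make_profile
from oracles import (
    oracle_loh,
    oracle_lst,
    oracle_tai,
    profile_to_chrom_segs,
)

MB = 1_000_000
L = 200 * MB  # toy chromosome length


class TestPreprocess:
    def test_merges_abutting_equal_states(self, toy_build):
        p = make_profile([("chr1", 1, 50 * MB, 1, 1), ("chr1", 50 * MB + 1, L, 1, 1)])
        out = preprocess_segments(p, toy_build)
        assert len(out.segments) == 1
        assert out.segments.iloc[0]["end"] == L

    def test_keeps_differing_states(self, toy_build):
        p = make_profile([("chr1", 1, 50 * MB, 2, 1), ("chr1", 50 * MB + 1, L, 1, 1)])
        assert len(preprocess_segments(p, toy_build).segments) == 2

    def test_idempotent(self, toy_build):
        p = make_profile(
            [("chr1", 1, 50 * MB, 2, 1), ("chr1", 50 * MB + 1, L, 1, 1)]
        )
        once = preprocess_segments(p, toy_build)
        twice = preprocess_segments(once, toy_build)
        pd.testing.assert_frame_equal(once.segments, twice.segments)

    def test_rejects_out_of_bounds(self, toy_build):
        p = make_profile([("chr1", 1, L + 5, 1, 1)])
        with pytest.raises(ValidationError, match="bounds"):
            preprocess_segments(p, toy_build)


class TestLoh:
    def test_diploid_genome_zero(self, diploid, toy_build):
        assert compute_loh(diploid, toy_build) == 0

    def test_interior_20mb_loh_counts(self, toy_build):
        p = make_profile(
            [
                ("chr1", 1, 30 * MB, 1, 1),
                ("chr1", 30 * MB + 1, 50 * MB, 2, 0),
                ("chr1", 50 * MB + 1, L, 1, 1),
            ]
        )
        assert compute_loh(p, toy_build) == 1

    def test_whole_chromosome_excluded(self, toy_build):
        p = make_profile([("chr1", 1, L, 1, 0)])
        assert compute_loh(p, toy_build) == 0

    def test_subthreshold_excluded(self, toy_build):
        p = make_profile(
            [
                ("chr1", 1, 30 * MB, 1, 1),
                ("chr1", 30 * MB + 1, 44 * MB, 1, 0),  # 14 Mb
                ("chr1", 44 * MB + 1, L, 1, 1),
            ]
        )
        assert compute_loh(p, toy_build) == 0

    def test_fragmented_run_counts_once(self, toy_build):
        """Two abutting B=0 segments with different A form one run."""
        p = make_profile(
            [
                ("chr1", 1, 30 * MB, 1, 1),
                ("chr1", 30 * MB + 1, 40 * MB, 1, 0),
                ("chr1", 40 * MB + 1, 50 * MB, 2, 0),
                ("chr1", 50 * MB + 1, L, 1, 1),
            ]
        )
        assert compute_loh(p, toy_build) == 1

    def test_homdel_dialect_switch(self, toy_build):
        p = make_profile(
            [
                ("chr1", 1, 30 * MB, 1, 1),
                ("chr1", 30 * MB + 1, 50 * MB, 0, 0),
                ("chr1", 50 * MB + 1, L, 1, 1),
            ]
        )
        assert compute_loh(p, toy_build) == 1
        no_homdel = PipelineConfig(loh_count_homdel=False)
        assert compute_loh(p, toy_build, no_homdel) == 0


class TestTai:
    def test_balanced_genome_zero(self, toy_build):
        p = make_profile(
            [("chr1", 1, 100 * MB, 1, 1), ("chr1", 100 * MB + 1, L, 2, 2)]
        )
        assert compute_tai(p, toy_build) == 0

    def test_q_telomeric_imbalance_counts(self, toy_build):
        p = make_profile(
            [("chr1", 1, 175 * MB, 1, 1), ("chr1", 175 * MB + 1, L, 2, 1)]
        )
        assert compute_tai(p, toy_build) == 1

    def test_centromere_crossing_excluded(self, toy_build):
        # imbalance from inside the centromere interval to the q telomere
        p = make_profile(
            [("chr1", 1, 100 * MB, 1, 1), ("chr1", 100 * MB + 1, L, 2, 1)]
        )
        assert compute_tai(p, toy_build) == 0

    def test_interior_imbalance_excluded(self, toy_build):
        p = make_profile(
            [
                ("chr1", 1, 30 * MB, 1, 1),
                ("chr1", 30 * MB + 1, 60 * MB, 2, 1),
                ("chr1", 60 * MB + 1, L, 1, 1),
            ]
        )
        assert compute_tai(p, toy_build) == 0

    def test_min_length_config(self, toy_build):
        p = make_profile(
            [("chr1", 1, 175 * MB, 1, 1), ("chr1", 175 * MB + 1, L, 2, 1)]
        )  # 25 Mb telomeric run
        assert compute_tai(p, toy_build, PipelineConfig(tai_min_length=30 * MB)) == 0


class TestLst:
    def test_uniform_chromosome_zero(self, diploid, toy_build):
        assert compute_lst(diploid, toy_build) == 0

    def test_single_junction(self, toy_build):
        p = make_profile(
            [("chr1", 1, 30 * MB, 1, 1), ("chr1", 30 * MB + 1, 60 * MB, 2, 1),
             ("chr1", 60 * MB + 1, 95 * MB - 1, 2, 1)]
        )
        # merged (2,1) piece: one junction at 30 Mb, both flanks >= 10 Mb
        assert compute_lst(p, toy_build) == 1

    def test_smoothing_removes_fragment(self, toy_build):
        p = make_profile(
            [
                ("chr1", 1, 12 * MB, 1, 1),
                ("chr1", 12 * MB + 1, 14 * MB, 2, 2),  # 2 Mb fragment
                ("chr1", 14 * MB + 1, 26 * MB, 1, 1),
            ]
        )
        assert compute_lst(p, toy_build) == 0

    def test_short_flank_does_not_count(self, toy_build):
        p = make_profile(
            [
                ("chr1", 1, 30 * MB, 1, 1),
                ("chr1", 30 * MB + 1, 35 * MB, 2, 2),  # 5 Mb: kept, but short
                ("chr1", 35 * MB + 1, 90 * MB, 1, 1),
            ]
        )
        assert compute_lst(p, toy_build) == 0


class TestScarScores:
    def test_hrdsum_and_cutpoint(self):
        from hrdkit.scars import ScarScores

        s = ScarScores("s", loh=10, tai=15, lst=17)
        assert s.hrdsum == 42
        assert s.hrd_positive(42.0)
        assert not ScarScores("s", 10, 15, 16).hrd_positive(42.0)

    def test_diploid_all_zero(self, diploid, toy_build):
        s = compute_scar_scores(diploid, toy_build)
        assert (s.loh, s.tai, s.lst, s.hrdsum) == (0, 0, 0, 0)
        assert not s.hrd_positive()


@pytest.mark.parametrize("seed", range(12))
def test_scores_match_bruteforce_oracles(seed, build):
    """Random unconstrained profiles score identically under the naive
    run/junction enumerators."""
    p = simulate_random_profile(build, seed=seed)
    segs = profile_to_chrom_segs(p)
    lengths = {c: build.length(c) for c in build.chromosomes}
    cens = {c: build.centromere(c) for c in build.chromosomes}
    assert compute_loh(p, build) == oracle_loh(segs, lengths)
    assert compute_tai(p, build) == oracle_tai(segs, lengths, cens)
    assert compute_lst(p, build) == oracle_lst(segs, lengths, cens)
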