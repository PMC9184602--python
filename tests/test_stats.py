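"""Association statistics against hand-computed and brute-force values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hrdkit.io_errors import ValidationError
from hrdkit.stats import (
    bh_fdr,
    delong_compare,
    fishers_method,
    gene_hrd_association,
    group_shift_test,
    loocv_youden,
    roc_auc,
    spearman,
    youden_cutpoint,
)

from oracles import oracle_auc


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0

    def test_constant_scores(self):
        r = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.auc == 0.5

    def test_hand_counted_example(self):
        # pos {3, 1}, neg {2, 0}: 3 concordant of 4 pairs
        r = roc_auc([3, 1, 2, 0], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(
            oracle_auc(scores[labels == 1], scores[labels == 0])
        )

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(3)
        r = roc_auc(rng.normal(size=40), rng.integers(0, 2, 40))
        assert (np.diff(r.tpr) >= 0).all()
        assert (np.diff(r.fpr) >= 0).all()


class TestDeLong:
    def test_identical_scores_p_one(self):
        scores = [1.0, 2, 3, 4, 5, 6]
        labels = [0, 0, 0, 1, 1, 1]
        diff, p = delong_compare(scores, scores, labels)
        assert diff == 0.0
        assert p == 1.0

    def test_structural_components_match_bruteforce(self):
        """Variance built from explicitly enumerated psi components."""
        rng = np.random.default_rng(8)
        s1 = rng.normal(size=20)
        s2 = rng.normal(size=20)
        labels = np.array([1] * 8 + [0] * 12)
        pos1, neg1 = s1[labels == 1], s1[labels == 0]
        pos2, neg2 = s2[labels == 1], s2[labels == 0]

        def comps(pos, neg):
            psi = np.zeros((len(pos), len(neg)))
            for i, x in enumerate(pos):
                for j, y in enumerate(neg):
                    psi[i, j] = 1.0 if x > y else (0.5 if x == y else 0.0)
            return psi.mean(axis=1), psi.mean(axis=0), psi.mean()

        v10_1, v01_1, a1 = comps(pos1, neg1)
        v10_2, v01_2, a2 = comps(pos2, neg2)
        s10 = np.cov(np.vstack([v10_1, v10_2]))
        s01 = np.cov(np.vstack([v01_1, v01_2]))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / 8 + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / 12
        z = (a1 - a2) / np.sqrt(var)
        expected_p = 2 * sps.norm.sf(abs(z))
        diff, p = delong_compare(s1, s2, labels)
        assert diff == pytest.approx(a1 - a2)
        assert p == pytest.approx(expected_p)

    def test_discriminating_vs_noise_scores(self):
        rng = np.random.default_rng(1)
        labels = np.array([1] * 40 + [0] * 40)
        good = labels * 3.0 + rng.normal(size=80)
        noise = rng.normal(size=80)
        diff, p = delong_compare(good, noise, labels)
        assert diff > 0.2
        assert p < 0.01


class TestYouden:
    def test_perfect_separation(self):
        r = youden_cutpoint([5, 3, 1, 2], [1, 1, 0, 0])
        assert r.youden_j == pytest.approx(1.0)
        assert r.cutpoint == 3  # lowest observed value achieving J = 1

    def test_tie_break_toward_higher_specificity(self):
        # pos {3, 1}, neg {2, 0}: J = 0.5 at c = 1 (spec .5) and c = 3 (spec 1)
        r = youden_cutpoint([3, 1, 2, 0], [1, 1, 0, 0])
        assert r.youden_j == pytest.approx(0.5)
        assert r.cutpoint == 3
        assert r.specificity == 1.0

    def test_constant_scores_j_zero(self):
        r = youden_cutpoint([4, 4, 4, 4], [1, 0, 1, 0])
        assert r.youden_j == pytest.approx(0.0)


class TestLoocv:
    def test_perfectly_separated_cohort(self):
        scores = [60, 65, 70, 80, 10, 15, 20, 25]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        out = loocv_youden(scores, labels, fixed_cutpoint=42)
        # the fixed rule is untouched by fold membership and stays perfect;
        # the refit rule misclassifies the held-out boundary positive (its
        # refit cutpoint is the smallest *remaining* positive), so one of
        # eight predictions fails: J = sens 3/4 + spec 1 - 1
        assert out["j_fixed"] == pytest.approx(1.0)
        assert out["j_loocv_optimal"] == pytest.approx(0.75)

    def test_optimal_beats_misplaced_fixed_cutpoint(self):
        """A cohort separating around 100 makes the fixed 42 rule useless."""
        rng = np.random.default_rng(2)
        pos = rng.normal(120, 5, 30)
        neg = rng.normal(80, 5, 30)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * 30 + [0] * 30)
        out = loocv_youden(scores, labels, fixed_cutpoint=42)
        assert out["j_loocv_optimal"] > out["j_fixed"]

    def test_minimal_cohort_runs(self):
        out = loocv_youden([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0], 4)
        assert np.isfinite(out["j_loocv_optimal"])


class TestGroupShift:
    def test_identical_groups(self):
        a = np.arange(20.0)
        fold, p = group_shift_test(a, a)
        assert fold == pytest.approx(1.0)
        assert p > 0.4

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(2, 1, 50)
        b = rng.normal(0, 1, 50)
        fold, p = group_shift_test(a, b)
        assert p < 0.05

    def test_zero_mean_pseudocount(self):
        fold, p = group_shift_test([2.0, 4.0], [0.0, 0.0])
        assert fold == pytest.approx(4.0)  # (3 + 1) / (0 + 1)
        assert np.isfinite(p)


class TestSpearman:
    def test_perfect_correlations(self):
        x = [1.0, 2, 3, 4, 5]
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        # d = (-1, 1, -1, 1, 0): d^2 sum = 4, rho = 1 - 24/120 = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-6)
        # d = (0, 0, -2, 1, 1): d^2 sum = 6, rho = 1 - 36/120 = 0.7
        rho2, _ = spearman([1, 2, 3, 4, 5], [1, 2, 5, 3, 4])
        assert rho2 == pytest.approx(0.7, abs=1e-6)

    def test_constant_vector_raises(self):
        with pytest.raises(ValidationError):
            spearman([1, 1, 1], [1, 2, 3])


class TestBhFdr:
    def test_hand_computed_stepup(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_dominates_raw_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=30)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])


class TestFishersMethod:
    def test_two_equal_pvalues(self):
        stat, p = fishers_method([0.05, 0.05])
        assert stat == pytest.approx(-2 * np.log(0.05 * 0.05))
        assert stat == pytest.approx(11.9829, abs=1e-3)
        assert p == pytest.approx(0.01752, abs=1e-4)

    def test_single_p_identity(self):
        _, p = fishers_method([0.37])
        assert p == pytest.approx(0.37, abs=1e-9)


class TestGeneHrdAssociation:
    @staticmethod
    def _cohort():
        # 20 tumors, one cancer type: gene G mutated exactly in the 10
        # HRD-positive tumors
        samples = [f"S{i}" for i in range(20)]
        tumors = pd.DataFrame(
            {
                "sample": samples,
                "cancer_type": "OV",
                "hrd_positive": [True] * 10 + [False] * 10,
            }
        )
        mutations = pd.DataFrame({"sample": samples[:10], "gene": "G"})
        return mutations, tumors

    def test_extreme_table_hypergeometric_tail(self):
        mutations, tumors = self._cohort()
        out = gene_hrd_association(mutations, tumors, prevalence_filter=0.05)
        row = out[(out["gene"] == "G") & (out["stratum"] == "OV")].iloc[0]
        # one-sided Fisher for 10/0/0/10 = 1 / C(20,10)
        assert row["p"] == pytest.approx(1 / 184756, rel=1e-6)

    def test_prevalence_filter_excludes_rare_gene(self):
        mutations, tumors = self._cohort()
        rare = pd.concat(
            [mutations, pd.DataFrame({"sample": ["S0"], "gene": ["RARE"]})],
            ignore_index=True,
        )
        out = gene_hrd_association(rare, tumors, prevalence_filter=0.10)
        assert "RARE" not in set(out["gene"])

    def test_two_strata_combined(self):
        samples = [f"S{i}" for i in range(40)]
        tumors = pd.DataFrame(
            {
                "sample": samples,
                "cancer_type": ["A"] * 20 + ["B"] * 20,
                "hrd_positive": ([True] * 10 + [False] * 10) * 2,
            }
        )
        mutations = pd.DataFrame(
            {"sample": samples[:10] + samples[20:30], "gene": "G"}
        )
        out = gene_hrd_association(mutations, tumors)
        combined = out[(out["gene"] == "G") & (out["stratum"] == "combined")].iloc[0]
        per = out[(out["gene"] == "G") & (out["stratum"] != "combined")]["p"]
        _, expected = fishers_method(per.to_numpy())
        assert combined["p"] == pytest.approx(expected)

    def test_subcohort_restriction(self):
        mutations, tumors = self._cohort()
        sub = pd.Series(False, index=tumors["sample"])
        sub[:15] = True
        out = gene_hrd_association(mutations, tumors, subcohort=sub)
        row = out[out["stratum"] == "OV"].iloc[0]
        assert row[["n11", "n10", "n01", "n00"]].sum() == 15
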