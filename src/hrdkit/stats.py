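"""Cohort association statistics.

ROC/AUC with one-sided rank-test significance, DeLong comparison of
paired AUCs, Youden-index cutpoint optimization with leave-one-out
cross-validation, one-sided group shift tests, Spearman correlation, and
the gene-versus-HRD association procedure (per-stratum Fisher exact
tests combined across strata by Fisher's method, Benjamini-Hochberg
adjusted across genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

from .io_errors import ValidationError

log = logging.getLogger(__name__)


def _check_two_groups(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both label groups must be non-empty")
    return pos, neg


@dataclass(frozen=True)
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_positive: int
    n_negative: int
    p_value: float  # one-sided rank test: positives have greater scores


def roc_auc(scores, labels) -> RocResult:
    """AUC as the concordance probability plus a one-sided rank-test p.

    AUC = (concordant pairs + ties / 2) / (n1 * n0), identical to the
    normalized Mann-Whitney U statistic.
    """
    pos, neg = _check_two_groups(np.asarray(scores), np.asarray(labels))
    res = sps.mannwhitneyu(pos, neg, alternative="greater")
    auc = res.statistic / (len(pos) * len(neg))
    fpr, tpr, _ = roc_curve(np.asarray(labels).astype(int), np.asarray(scores, dtype=float))
    return RocResult(float(auc), fpr, tpr, len(pos), len(neg), float(res.pvalue))


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos, neg = _check_two_groups(scores, labels)
    # psi(x, y) = 1 if x > y, 0.5 if tie, 0 otherwise
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def delong_compare(scores1, scores2, labels) -> tuple[float, float]:
    """Two-sided DeLong test for paired AUC difference.

    Returns (AUC1 - AUC2, p-value).
    """
    scores1 = np.asarray(scores1, dtype=float)
    scores2 = np.asarray(scores2, dtype=float)
    labels = np.asarray(labels).astype(bool)
    v10_1, v01_1, auc1 = _delong_components(scores1, labels)
    v10_2, v01_2, auc2 = _delong_components(scores2, labels)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc1 - auc2
    if var <= 0:
        if diff == 0:
            return 0.0, 1.0
        raise ValidationError("degenerate DeLong variance with non-zero AUC difference")
    z = diff / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return float(diff), float(p)


@dataclass(frozen=True)
class CutpointResult:
    cutpoint: float
    youden_j: float
    sensitivity: float
    specificity: float


def youden_cutpoint(scores, labels) -> CutpointResult:
    """Cutpoint maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the observed score values; samples are called
    positive at score >= cutpoint. Ties are broken toward higher
    specificity, then toward the lower cutpoint.
    """
    pos, neg = _check_two_groups(np.asarray(scores), np.asarray(labels))
    best: CutpointResult | None = None
    for c in np.unique(np.concatenate([pos, neg])):
        sens = float((pos >= c).mean())
        spec = float((neg < c).mean())
        j = sens + spec - 1
        cand = CutpointResult(float(c), j, sens, spec)
        if (
            best is None
            or cand.youden_j > best.youden_j + 1e-12
            or (
                abs(cand.youden_j - best.youden_j) <= 1e-12
                and (
                    cand.specificity > best.specificity + 1e-12
                    or (
                        abs(cand.specificity - best.specificity) <= 1e-12
                        and cand.cutpoint < best.cutpoint
                    )
                )
            )
        ):
            best = cand
    assert best is not None
    return best


def _confusion_j(pred: np.ndarray, labels: np.ndarray) -> float:
    labels = labels.astype(bool)
    sens = pred[labels].mean() if labels.any() else np.nan
    spec = (~pred[~labels]).mean() if (~labels).any() else np.nan
    return float(sens + spec - 1)


def loocv_youden(scores, labels, fixed_cutpoint: float = 42.0) -> dict:
    """Leave-one-out comparison of the refit-optimal vs a fixed cutpoint.

    For each held-out sample the cutpoint is re-optimized on the rest and
    the held-out sample classified; the aggregated predictions yield one
    cross-validated J per rule.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.sum() < 3 or (~labels).sum() < 3:
        raise ValidationError("leave-one-out needs at least 3 samples per class")
    n = len(scores)
    pred_opt = np.zeros(n, dtype=bool)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        c = youden_cutpoint(scores[mask], labels[mask]).cutpoint
        pred_opt[i] = scores[i] >= c
    pred_fixed = scores >= fixed_cutpoint
    return {
        "j_loocv_optimal": _confusion_j(pred_opt, labels),
        "j_fixed": _confusion_j(pred_fixed, labels),
        "fixed_cutpoint": float(fixed_cutpoint),
    }


def group_shift_test(group_a, group_b) -> tuple[float, float]:
    """Fold change mean(A)/mean(B) and one-sided rank-sum p for A > B.

    A pseudo-count of 1 enters both means when mean(B) is zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    if b.mean() == 0:
        fold = (a.mean() + 1) / (b.mean() + 1)
    else:
        fold = a.mean() / b.mean()
    p = float(sps.mannwhitneyu(a, b, alternative="greater").pvalue)
    return float(fold), p


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p (ties mid-ranked)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("spearman needs paired vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValidationError("spearman undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fishers_method(pvalues) -> tuple[float, float]:
    """Combine independent p-values: -2 sum(ln p) ~ chi2 with 2k df."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values to combine")
    stat, combined = sps.combine_pvalues(p, method="fisher")
    return float(stat), float(combined)


def gene_hrd_association(
    mutations: pd.DataFrame,
    tumors: pd.DataFrame,
    prevalence_filter: float = 0.05,
    fdr: float = 0.10,
    subcohort: pd.Series | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Association of per-gene mutation status with HRD positivity.

    ``mutations``: long table (sample, gene) of mutated genes.
    ``tumors``: one row per sample with columns sample, cancer_type,
    hrd_positive. ``subcohort``: optional boolean filter aligned on
    sample (e.g. restriction to tumors without relevant HRR alterations).

    Per cancer type a 2x2 Fisher exact test (default one-sided, testing
    enrichment of mutations among HRD-positive tumors); strata without
    any HRD-positive tumor are skipped. Gene-level p-values combine the
    strata by Fisher's method and are BH-adjusted across genes. Genes
    mutated in fewer than ``prevalence_filter`` of the analyzed samples
    are excluded.
    """
    tumors = tumors.copy()
    if subcohort is not None:
        keep = tumors["sample"].map(subcohort).fillna(False).astype(bool)
        tumors = tumors[keep]
    samples = set(tumors["sample"])
    mutations = mutations[mutations["sample"].isin(samples)]
    n = len(tumors)
    if n == 0:
        raise ValidationError("no tumors to analyze")
    prevalence = mutations.groupby("gene")["sample"].nunique() / n
    genes = sorted(prevalence[prevalence >= prevalence_filter].index)
    mutated: dict[str, set] = {
        g: set(mutations.loc[mutations["gene"] == g, "sample"]) for g in genes
    }
    rows = []
    for gene in genes:
        stratum_ps = []
        for cancer_type, grp in tumors.groupby("cancer_type"):
            hrd = grp["hrd_positive"].astype(bool).to_numpy()
            if not hrd.any():
                log.warning("stratum %s has no HRD-positive tumors; skipped", cancer_type)
                continue
            mut = grp["sample"].isin(mutated[gene]).to_numpy()
            table = [
                [int((mut & hrd).sum()), int((mut & ~hrd).sum())],
                [int((~mut & hrd).sum()), int((~mut & ~hrd).sum())],
            ]
            odds, p = sps.fisher_exact(table, alternative=alternative)
            stratum_ps.append(p)
            rows.append(
                {
                    "gene": gene,
                    "stratum": cancer_type,
                    "n11": table[0][0],
                    "n10": table[0][1],
                    "n01": table[1][0],
                    "n00": table[1][1],
                    "odds_ratio": odds,
                    "p": p,
                }
            )
        if stratum_ps:
            _, combined = fishers_method(stratum_ps)
            rows.append(
                {
                    "gene": gene,
                    "stratum": "combined",
                    "n11": np.nan,
                    "n10": np.nan,
                    "n01": np.nan,
                    "n00": np.nan,
                    "odds_ratio": np.nan,
                    "p": combined,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        combined_mask = out["stratum"] == "combined"
        q = pd.Series(np.nan, index=out.index)
        q[combined_mask] = bh_fdr(out.loc[combined_mask, "p"].to_numpy())
        out["q"] = q
        out["significant"] = out["q"] < fdr
    return out
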