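"""BRCA1 promoter hypermethylation calling and CpG site selection.

Methylation status is called from beta-values at four indicative CpG
probes in the BRCA1 promoter (cg04658354, cg08993267, cg10893007,
cg19531713): strong if any beta >= 0.6, moderate if any beta >= 0.2 but
none >= 0.6, unmethylated otherwise. Missing betas are ignored; a sample
with no measurable probe is unevaluable.

The indicative sites can also be re-derived from data: promoter probes
whose beta-values correlate strongly negatively (Spearman) with BRCA1
mRNA expression at BH-controlled FDR.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .io_errors import ValidationError
from .stats import bh_fdr

log = logging.getLogger(__name__)

#: the four indicative BRCA1 promoter probes
INDICATIVE_CPGS = ("cg04658354", "cg08993267", "cg10893007", "cg19531713")

STATUSES = ("strong", "moderate", "unmethylated", "unevaluable")


def call_brca1_methylation(
    betas: pd.Series | np.ndarray | list,
    config: PipelineConfig | None = None,
) -> str:
    """Methylation status from the indicative-site betas of one sample."""
    config = config or PipelineConfig()
    values = np.asarray(pd.Series(betas).dropna(), dtype=float)
    if values.size == 0:
        return "unevaluable"
    if ((values < 0) | (values > 1)).any():
        raise ValidationError("beta values must lie in [0, 1]")
    top = values.max()
    if top >= config.methylation_strong:
        return "strong"
    if top >= config.methylation_moderate:
        return "moderate"
    return "unmethylated"


def call_methylation_matrix(
    matrix: pd.DataFrame,
    probes: tuple[str, ...] = INDICATIVE_CPGS,
    config: PipelineConfig | None = None,
) -> pd.Series:
    """Per-sample methylation status from a probe x sample beta matrix.

    Probes absent from the matrix are ignored (call made from available
    indicative probes).
    """
    config = config or PipelineConfig()
    present = [p for p in probes if p in matrix.index]
    if not present:
        return pd.Series("unevaluable", index=matrix.columns, name="methylation")
    sub = matrix.loc[present]
    return pd.Series(
        {s: call_brca1_methylation(sub[s], config) for s in matrix.columns},
        name="methylation",
    )


def select_indicative_cpgs(
    betas: pd.DataFrame,
    expression: pd.Series,
    rho_threshold: float = -0.3,
    fdr: float = 0.10,
) -> list[str]:
    """Probes anticorrelated with expression at BH FDR.

    A probe is selected when its Spearman rho with the per-sample
    expression is <= ``rho_threshold`` and the two-sided p-value passes
    Benjamini-Hochberg at ``fdr``.
    """
    samples = [s for s in betas.columns if s in expression.index]
    if len(samples) < 3:
        raise ValidationError("need at least 3 paired samples for site selection")
    expr = expression.loc[samples].to_numpy(dtype=float)
    rhos, pvals, probes = [], [], []
    for probe, row in betas[samples].iterrows():
        values = row.to_numpy(dtype=float)
        ok = ~np.isnan(values)
        if ok.sum() < 3:
            continue
        rho, p = stats.spearmanr(values[ok], expr[ok])
        probes.append(probe)
        rhos.append(rho)
        pvals.append(p)
    if not probes:
        return []
    q = bh_fdr(np.asarray(pvals))
    selected = [
        probe
        for probe, rho, qv in zip(probes, rhos, q)
        if rho <= rho_threshold and qv < fdr
    ]
    log.debug("selected %d/%d probes as indicative", len(selected), len(probes))
    return selected
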