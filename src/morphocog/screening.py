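"""Atrophy screening: one-sided rank-sum tests with FDR control.

Each region's control residuals are compared with its case residuals by a
two-sample Wilcoxon rank-sum test, one-sided in the atrophy direction
(controls stochastically larger).  Benjamini-Hochberg step-up across all
regions controls the false discovery rate; surviving regions, in their
original column order, form the sMRI predictor set for the cognition models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .data_model import DegenerateDataWarning, ResidualTable, ValidationError

logger = logging.getLogger(__name__)

_SIDES = {"greater", "less", "two-sided"}


def wilcoxon_rank_sum(
    sample_a: np.ndarray, sample_b: np.ndarray, side: str = "greater"
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test; returns (rank-sum statistic, p).

    The statistic is the rank sum of ``sample_a`` with midranks for ties.
    The p-value is exact (full enumeration of rank assignments) when both
    samples have <= 10 observations and no ties occur; otherwise the normal
    approximation with continuity and tie correction is used.  ``side`` is
    the alternative for the location of ``sample_a`` relative to ``sample_b``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if side not in _SIDES:
        raise ValidationError(f"side must be one of {sorted(_SIDES)}")
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    pooled = np.concatenate([a, b])
    n1 = a.size
    if np.all(pooled == pooled[0]):
        warnings.warn(
            "all values identical across both samples; rank-sum test is "
            "degenerate (p = 1)",
            DegenerateDataWarning,
            stacklevel=2,
        )
        return float(n1 * (a.size + b.size + 1) / 2), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative=side, method=method, use_continuity=True)
    rank_sum = float(res.statistic) + n1 * (n1 + 1) / 2.0
    return rank_sum, float(res.pvalue)


def benjamini_hochberg(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (q_values, reject flags).

    q-values are the adjusted p-values after cumulative-minimum enforcement,
    so rejection at level ``alpha`` is exactly ``q <= alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


@dataclass(frozen=True)
class ScreenResult:
    region_name: str
    statistic: float
    p_value: float
    q_value: float
    significant: bool
    direction: str  # "atrophy" | "none"


def screen_regions(
    residuals: ResidualTable, alpha: float = 0.05
) -> tuple[list[ScreenResult], list[str]]:
    """Per-region one-sided screen (control residuals > case residuals).

    Returns the per-region results (original column order) and the selected
    predictor set: regions significant after BH across all tested regions.
    """
    labels = set(residuals.group_labels.unique())
    if not {"control", "case"} <= labels:
        raise ValidationError("residual table must contain both groups")

    stats, pvals = [], []
    for region in residuals.region_names:
        ctrl, case = residuals.by_group(region)
        s, p = wilcoxon_rank_sum(ctrl, case, side="greater")
        stats.append(s)
        pvals.append(p)
    q, reject = benjamini_hochberg(np.asarray(pvals), alpha=alpha)

    results = [
        ScreenResult(
            region_name=region,
            statistic=stats[i],
            p_value=pvals[i],
            q_value=float(q[i]),
            significant=bool(reject[i]),
            direction="atrophy" if reject[i] else "none",
        )
        for i, region in enumerate(residuals.region_names)
    ]
    predictor_set = [r.region_name for r in results if r.significant]
    if not predictor_set:
        warnings.warn(
            "no region survived FDR screening; predictor set is empty",
            UserWarning,
            stacklevel=2,
        )
    logger.info(
        "screening selected %d/%d regions at FDR %.3g",
        len(predictor_set),
        len(results),
        alpha,
    )
    return results, predictor_set
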