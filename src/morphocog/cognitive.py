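"""Cognitive score utilities and covariate-adjusted group comparisons.

Timing precision is scored as the reciprocal of the within-subject standard
deviation of intertap intervals during unpaced continuation tapping (1/ms).
Group differences on each of the five outcomes are tested by ANCOVA —
ordinary least squares of outcome on group plus age, sex, education and
visit count — with the group coefficient (case minus control) as the
adjusted effect; the five outcomes are tested without multiplicity
correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import ValidationError

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Input has no variance where variance is required."""


def timing_precision(intertap_intervals: Sequence[float]) -> float:
    """Reciprocal of the sample SD (denominator n-1) of intertap intervals.

    Intervals are in ms, so the score is in 1/ms; larger = more precise
    tapping.  At least 3 intervals are required; identical intervals give a
    zero SD and the score is undefined.
    """
    x = np.asarray(intertap_intervals, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 intertap intervals")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError(
            "all intertap intervals identical; precision undefined"
        )
    return 1.0 / sd


@dataclass(frozen=True)
class GroupComparisonResult:
    outcome: str
    effect: float  # adjusted case - control difference, outcome units
    t_statistic: float
    p_value: float
    covariates: tuple[str, ...]


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns that are linear combinations of the preceding ones
        culprits = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                culprits.append(design.columns[j])
        raise ValidationError(f"design matrix is rank deficient; collinear column(s): {culprits}")


def ancova_group_test(
    outcome: np.ndarray,
    group_labels: Sequence[str],
    covariates: pd.DataFrame,
    outcome_name: str = "outcome",
) -> GroupComparisonResult:
    """OLS ANCOVA: outcome ~ group + covariates; reports the group term.

    ``group_labels`` must contain both "control" and "case"; the coefficient
    is the adjusted case-minus-control difference.  Covariates must be
    numeric and complete (sex pre-coded as an indicator).
    """
    y = np.asarray(outcome, dtype=float)
    g = pd.Series(group_labels).astype(str)
    if set(g.unique()) != {"control", "case"}:
        raise ValidationError("both groups must be represented")
    if covariates.isna().any().any():
        raise ValidationError("covariates must be complete")
    design = pd.DataFrame(index=covariates.index)
    design["const"] = 1.0
    design["group_case"] = (g == "case").to_numpy(dtype=float)
    for col in covariates.columns:
        design[col] = covariates[col].to_numpy(dtype=float)
    _check_full_rank(design)
    fit = sm.OLS(y, design).fit()
    return GroupComparisonResult(
        outcome=outcome_name,
        effect=float(fit.params["group_case"]),
        t_statistic=float(fit.tvalues["group_case"]),
        p_value=float(fit.pvalues["group_case"]),
        covariates=tuple(covariates.columns),
    )


@dataclass(frozen=True)
class VisitEffectResult:
    p_visit: float
    p_interaction: float
    p_group: float


def visit_effect_check(
    outcome: np.ndarray,
    group_labels: Sequence[str],
    visit_count: np.ndarray,
    covariates: pd.DataFrame,
) -> VisitEffectResult | None:
    """Practice-effect pre-check: outcome ~ visit + group + visit:group + covs.

    Returns the visit main-effect, interaction and group p-values so the
    caller can decide whether to retain visit count as a covariate (the
    study design retains it regardless).  With a single distinct visit level
    the check is skipped (returns None with a notice).
    """
    y = np.asarray(outcome, dtype=float)
    v = np.asarray(visit_count, dtype=float)
    if np.unique(v).size < 2:
        warnings.warn(
            "single visit level; visit-effect check skipped", UserWarning,
            stacklevel=2,
        )
        return None
    g = (pd.Series(group_labels).astype(str) == "case").to_numpy(dtype=float)
    design = pd.DataFrame(index=covariates.index)
    design["const"] = 1.0
    design["visit"] = v
    design["group_case"] = g
    design["visit_x_group"] = v * g
    for col in covariates.columns:
        design[col] = covariates[col].to_numpy(dtype=float)
    _check_full_rank(design)
    fit = sm.OLS(y, design).fit()
    return VisitEffectResult(
        p_visit=float(fit.pvalues["visit"]),
        p_interaction=float(fit.pvalues["visit_x_group"]),
        p_group=float(fit.pvalues["group_case"]),
    )


def group_summary(
    outcomes: pd.DataFrame, group_labels: Sequence[str]
) -> pd.DataFrame:
    """Mean (SD) per group for each outcome column."""
    g = pd.Series(group_labels, index=outcomes.index).astype(str)
    rows = []
    for col in outcomes.columns:
        for grp in ("control", "case"):
            vals = outcomes.loc[g == grp, col].dropna()
            rows.append(
                {
                    "outcome": col,
                    "group": grp,
                    "n": int(vals.size),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)
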