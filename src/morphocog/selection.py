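"""Parsimonious top-k model selection by nested out-of-bag MSE curves.

Following the nested-model variable-selection strategy for random forests,
models using the top-1, top-2, ..., top-m ranked sMRI variables (always with
the four covariates) are each fitted repeatedly; the mean out-of-bag MSE per
model size traces a curve whose minimum marks the best-performing size.
Because that minimum is often shallow, the default choice applies the
one-standard-error rule: the smallest k whose mean MSE is within one SE of
the minimum — a reproducible formalization of choosing the smaller model
when two MSEs are "very close".  ``strict_min`` takes the literal argmin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor

from .data_model import ValidationError
from .importance import MIN_SAMPLES_LEAF, ImportanceRanking, mtry, tree_oob_indices

logger = logging.getLogger(__name__)


@dataclass
class SelectionCurve:
    k: np.ndarray
    mean_mse: np.ndarray
    mse_se: np.ndarray  # SD over runs / sqrt(n_runs)
    n_runs: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.mean_mse)):
            raise ValidationError("mean MSE must be finite for every k")

    @property
    def k_min(self) -> int:
        """Model size minimizing mean OOB MSE (smallest k on exact ties)."""
        return int(self.k[int(np.argmin(self.mean_mse))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k, "mean_mse": self.mean_mse, "mse_se": self.mse_se}
        )


def oob_mse(forest: RandomForestRegressor, y: np.ndarray) -> float:
    """Out-of-bag MSE of a fitted forest, over subjects with OOB coverage."""
    pred = forest.oob_prediction_
    n = y.shape[0]
    covered = np.zeros(n, dtype=bool)
    for tree in forest.estimators_:
        covered[tree_oob_indices(tree, n)] = True
    if not covered.any():
        raise ValidationError("no observation has out-of-bag coverage")
    return float(np.mean((y[covered] - pred[covered]) ** 2))


def build_curve(
    data: pd.DataFrame,
    outcome: str,
    ranking: ImportanceRanking,
    covariates: Sequence[str],
    n_runs: int = 200,
    n_trees: int = 5000,
    seed: int = 0,
    max_k: Optional[int] = None,
    n_jobs: int = 1,
) -> SelectionCurve:
    """Mean OOB MSE over ``n_runs`` fresh forest fits for each top-k model.

    Model k uses the k best variables by mean rank plus all covariates; the
    covariates do not count toward k.
    """
    if n_runs < 2:
        raise ValidationError("n_runs must be >= 2")
    order = ranking.ordered_variables
    if not order:
        raise ValidationError("ranking contains no variables")
    m = len(order) if max_k is None else min(max_k, len(order))
    covariates = sorted(covariates)
    y = data[outcome].to_numpy(dtype=float)

    ks = np.arange(1, m + 1)
    mean_mse = np.empty(m)
    mse_se = np.empty(m)
    for i, k in enumerate(ks):
        cols = sorted(order[:k]) + covariates
        X = np.ascontiguousarray(data[cols].to_numpy(dtype=float))
        mses = np.empty(n_runs)
        for run in range(n_runs):
            rs = int(
                np.random.SeedSequence([seed, int(k), run]).generate_state(1)[0]
                % (2**31)
            )
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=mtry(len(cols)),
                min_samples_leaf=MIN_SAMPLES_LEAF,
                oob_score=True,
                random_state=rs,
                n_jobs=n_jobs,
            )
            forest.fit(X, y)
            mses[run] = oob_mse(forest, y)
        mean_mse[i] = mses.mean()
        mse_se[i] = mses.std(ddof=1) / np.sqrt(n_runs)
    return SelectionCurve(k=ks, mean_mse=mean_mse, mse_se=mse_se, n_runs=n_runs)


def choose_k(curve: SelectionCurve, parsimony_rule: str = "one_se") -> int:
    """Select the model size from a curve.

    ``strict_min`` returns the argmin; ``one_se`` returns the smallest k with
    mean MSE within one standard error of the minimum (never larger than the
    argmin).
    """
    k_min = curve.k_min
    if parsimony_rule == "strict_min":
        return k_min
    if parsimony_rule != "one_se":
        raise ValidationError(f"unknown parsimony rule {parsimony_rule!r}")
    i_min = int(np.argmin(curve.mean_mse))
    threshold = curve.mean_mse[i_min] + curve.mse_se[i_min]
    eligible = np.nonzero(curve.mean_mse <= threshold)[0]
    return int(curve.k[eligible[0]])


def report_selected(
    ranking: ImportanceRanking,
    k_chosen: int,
    data: pd.DataFrame,
    outcome: str,
    rho_threshold: float = 0.1,
) -> pd.DataFrame:
    """Ranked table of the chosen top-k variables with direction flags.

    For each selected region, the Spearman correlation between its
    morphometry and the outcome (case group) is reported; atrophy semantics
    (thinner/smaller morphometry <-> worse performance) imply a positive
    correlation, so rho >= +threshold is flagged ``consistent``,
    rho <= -threshold ``inconsistent`` and |rho| < threshold
    ``indeterminate``.
    """
    if k_chosen < 1:
        raise ValidationError("k_chosen must be >= 1")
    order = ranking.ordered_variables[:k_chosen]
    y = data[outcome].to_numpy(dtype=float)
    rows = []
    for rank, var in enumerate(order, start=1):
        rho = spearmanr(data[var].to_numpy(dtype=float), y).statistic
        rho = float(rho) if np.isfinite(rho) else 0.0
        if rho >= rho_threshold:
            flag = "consistent"
        elif rho <= -rho_threshold:
            flag = "inconsistent"
        else:
            flag = "indeterminate"
        rows.append(
            {
                "rank": rank,
                "variable": var,
                "mean_rank": float(ranking.mean_rank[var]),
                "mean_importance": float(ranking.mean_importance[var]),
                "spearman_rho": rho,
                "direction": flag,
            }
        )
    return pd.DataFrame(rows)
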