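"""Permutation variable importance and repeated-forest stability ranking.

A random-forest regression of one cognitive outcome on the screened sMRI
regions plus the four demographic covariates is fitted many times; within
each fit, every predictor's importance is the mean increase in out-of-bag
mean squared error across trees when that predictor's values are permuted
among each tree's own OOB observations.  Because a single forest's ranking
is itself a random quantity, the fit is repeated (fresh bootstrap draws and
permutations each time) and each sMRI variable's rank is averaged over
repetitions; covariates stay in every model as confound adjustment but do
not compete in the ranking.

Permutations are keyed to (master seed, repetition, variable name, tree), so
results do not depend on the order predictor columns are supplied in, and an
independent implementation can reproduce the exact permutation sequence.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestRegressor

from .data_model import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ForestConfig:
    """Settings for the repeated-forest ranking stage.

    Defaults are the full-scale analysis settings (5000 trees, 1000
    repetitions); reduced values are used for testing and should be recorded
    in run metadata.  ``mtry`` follows the regression default max(1, p // 3)
    with p counting all predictors, covariates included.
    """

    n_bootstrap_trees: int = 5000
    n_repetitions: int = 1000
    importance_mode: str = "raw_increase"  # raw_increase | scaled
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_bootstrap_trees < 1 or self.n_repetitions < 1:
            raise ValidationError("tree and repetition counts must be >= 1")
        if self.importance_mode not in ("raw_increase", "scaled"):
            raise ValidationError(
                f"unknown importance_mode {self.importance_mode!r}"
            )


#: Minimum observations per leaf for all regression forests in the pipeline,
#: matching the R randomForest regression default (nodesize = 5).
MIN_SAMPLES_LEAF = 5


def mtry(n_predictors: int) -> int:
    return max(1, n_predictors // 3)


def _name_key(name: str) -> int:
    """Stable 31-bit key for a variable name (keeps permutations tied to the
    variable, not its column position)."""
    return zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF


def tree_oob_indices(tree, n_samples: int) -> np.ndarray:
    """Indices of the observations left out of one tree's bootstrap sample."""
    try:  # sklearn's own helper, signature as of 1.9
        from sklearn.ensemble._forest import _generate_unsampled_indices

        return np.asarray(
            _generate_unsampled_indices(tree.random_state, n_samples, n_samples, None)
        )
    except (ImportError, TypeError):
        sampled = np.random.RandomState(tree.random_state).randint(
            0, n_samples, n_samples
        )
        mask = np.ones(n_samples, dtype=bool)
        mask[sampled] = False
        return np.nonzero(mask)[0]


def _permutation_rng(seed: int, rep: int, var_key: int, tree_idx: int):
    return np.random.default_rng(
        np.random.SeedSequence([seed, rep, var_key, tree_idx])
    )


def permutation_importance(
    forest: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    var_names: Optional[Sequence[str]] = None,
    seed: int = 0,
    rep: int = 0,
    mode: str = "raw_increase",
) -> np.ndarray:
    """Per-variable OOB permutation importance of a fitted forest.

    For each tree t and variable v: predict the tree's OOB observations with
    v's values permuted (a fresh permutation per (v, t)) and record the
    increase of that tree's OOB MSE over its unpermuted baseline.  The raw
    importance is the average increase over trees (units: outcome squared);
    ``scaled`` divides by the standard error over trees, as some forest
    implementations report.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    keys = (
        [_name_key(name) for name in var_names]
        if var_names is not None
        else list(range(p))
    )
    if var_names is not None and len(var_names) != p:
        raise ValidationError("var_names length must match number of columns")
    constant = [j for j in range(p) if np.all(X[:, j] == X[0, j])]
    if constant:
        warnings.warn(
            f"predictor column(s) {constant} are constant; their permutation "
            "importance is 0 by construction",
            UserWarning,
            stacklevel=2,
        )

    n_trees = len(forest.estimators_)
    deltas = np.empty((n_trees, p))
    for t, tree in enumerate(forest.estimators_):
        oob = tree_oob_indices(tree, n)
        if oob.size == 0:
            deltas[t] = 0.0
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        m = oob.size
        # one prediction call per tree: block 0 = baseline, block j+1 = X_oob
        # with column j permuted
        stacked = np.tile(X_oob, (p + 1, 1))
        for j in range(p):
            perm = _permutation_rng(seed, rep, keys[j], t).permutation(m)
            stacked[(j + 1) * m : (j + 2) * m, j] = X_oob[perm, j]
        preds = tree.predict(stacked).reshape(p + 1, m)
        mse = np.mean((preds - y_oob[None, :]) ** 2, axis=1)
        deltas[t] = mse[1:] - mse[0]

    raw = deltas.mean(axis=0)
    if mode == "raw_increase":
        return raw
    sd = deltas.std(axis=0, ddof=1) if n_trees > 1 else np.zeros(p)
    se = sd / np.sqrt(n_trees)
    return np.where(se > 0, raw / np.where(se > 0, se, 1.0), 0.0)


@dataclass
class ImportanceRanking:
    """Aggregated ranking of the sMRI predictors over repetitions.

    ``mean_rank`` is over per-repetition midrank positions (1 = most
    important); final ordering breaks mean-rank ties by higher mean
    importance, then by name.
    """

    variables: list[str]  # sMRI variables, canonical (sorted) order
    mean_rank: pd.Series = field(repr=False)
    mean_importance: pd.Series = field(repr=False)
    rank_sd: pd.Series = field(repr=False)
    n_repetitions: int = 0
    rank_matrix: Optional[np.ndarray] = None  # repetitions x variables

    @property
    def ordered_variables(self) -> list[str]:
        order = sorted(
            self.variables,
            key=lambda v: (self.mean_rank[v], -self.mean_importance[v], v),
        )
        return order

    def to_frame(self) -> pd.DataFrame:
        order = self.ordered_variables
        return pd.DataFrame(
            {
                "variable": order,
                "mean_rank": [self.mean_rank[v] for v in order],
                "mean_importance": [self.mean_importance[v] for v in order],
                "rank_sd": [self.rank_sd[v] for v in order],
            }
        )


def rank_variables(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    covariates: Sequence[str],
    config: ForestConfig,
) -> ImportanceRanking:
    """Rank sMRI predictors of one outcome by repeated permutation importance.

    ``data`` holds one row per subject with the outcome, the sMRI predictor
    columns, and numeric covariate columns.  Covariates enter every forest
    (and count toward mtry) but are excluded from the ranking.
    """
    predictors = list(predictors)
    covariates = list(covariates)
    if not predictors:
        raise ValidationError("predictor set is empty")
    if len(data) < 30:
        raise ValidationError("need at least 30 subjects to rank predictors")
    missing = [c for c in [outcome, *predictors, *covariates] if c not in data.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")

    # canonical column order: results must not depend on supplied order
    smri = sorted(predictors)
    cols = smri + sorted(covariates)
    X = np.ascontiguousarray(data[cols].to_numpy(dtype=float))
    y = data[outcome].to_numpy(dtype=float)
    p = len(cols)
    m = len(smri)
    max_features = mtry(p)

    rank_matrix = np.empty((config.n_repetitions, m))
    imp_matrix = np.empty((config.n_repetitions, m))
    for rep in range(config.n_repetitions):
        try:
            rs = int(
                np.random.SeedSequence([config.seed, rep]).generate_state(1)[0]
                % (2**31)
            )
            forest = RandomForestRegressor(
                n_estimators=config.n_bootstrap_trees,
                max_features=max_features,
                min_samples_leaf=MIN_SAMPLES_LEAF,
                random_state=rs,
                n_jobs=config.n_jobs,
                bootstrap=True,
            )
            forest.fit(X, y)
            imp = permutation_importance(
                forest,
                X,
                y,
                var_names=cols,
                seed=config.seed,
                rep=rep,
                mode=config.importance_mode,
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"repetition {rep} failed: {exc}") from exc
        smri_imp = imp[:m]
        rank_matrix[rep] = rankdata(-smri_imp, method="average")
        imp_matrix[rep] = smri_imp

    mean_rank = pd.Series(rank_matrix.mean(axis=0), index=smri)
    mean_importance = pd.Series(imp_matrix.mean(axis=0), index=smri)
    rank_sd = pd.Series(rank_matrix.std(axis=0, ddof=1 if config.n_repetitions > 1 else 0), index=smri)
    return ImportanceRanking(
        variables=smri,
        mean_rank=mean_rank,
        mean_importance=mean_importance,
        rank_sd=rank_sd,
        n_repetitions=config.n_repetitions,
        rank_matrix=rank_matrix,
    )
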