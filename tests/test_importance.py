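"""Permutation importance against a brute-force oracle; ranking invariants."""

import zlib

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from morphocog.importance import (
    ForestConfig,
    mtry,
    permutation_importance,
    rank_variables,
    tree_oob_indices,
)


def brute_force_importance(forest, X, y, var_names, seed, rep=0):
    """Independent recomputation: re-derive each tree's bootstrap sample from
    its stored random state, re-predict OOB cases one row at a time before
    and after permuting each variable (same documented permutation keys:
    SeedSequence([seed, rep, crc32(name), tree_index]))."""
    n, p = X.shape
    deltas = []
    for t, tree in enumerate(forest.estimators_):
        sampled = set(np.random.RandomState(tree.random_state).randint(0, n, n).tolist())
        oob = [i for i in range(n) if i not in sampled]
        if not oob:
            deltas.append([0.0] * p)
            continue
        base = [float(tree.predict(X[i].reshape(1, -1))[0]) for i in oob]
        base_mse = float(np.mean([(y[i] - b) ** 2 for i, b in zip(oob, base)]))
        row = []
        for j, name in enumerate(var_names):
            key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
            rng = np.random.default_rng(np.random.SeedSequence([seed, rep, key, t]))
            perm = rng.permutation(len(oob))
            permuted_col = [X[oob[k], j] for k in perm]
            errs = []
            for pos, i in enumerate(oob):
                xi = X[i].copy()
                xi[j] = permuted_col[pos]
                pred = float(tree.predict(xi.reshape(1, -1))[0])
                errs.append((y[i] - pred) ** 2)
            row.append(float(np.mean(errs)) - base_mse)
        deltas.append(row)
    return np.mean(np.array(deltas), axis=0)


@pytest.fixture()
def tiny_fit():
    rng = np.random.default_rng(7)
    n, p = 12, 3
    X = rng.normal(size=(n, p))
    y = 2.0 * X[:, 0] + rng.normal(0, 0.3, n)
    names = ["alpha", "beta", "gamma"]
    return X, y, names


@pytest.mark.parametrize("n_trees", [1, 5])
def test_importance_matches_brute_force(tiny_fit, n_trees):
    X, y, names = tiny_fit
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=3).fit(X, y)
    ours = permutation_importance(forest, X, y, var_names=names, seed=11)
    oracle = brute_force_importance(forest, X, y, names, seed=11)
    np.testing.assert_allclose(ours, oracle, rtol=1e-12, atol=1e-12)


def test_signal_variable_dominates():
    rng = np.random.default_rng(1)
    n = 80
    X = rng.normal(size=(n, 4))
    y = X[:, 1].copy()  # exact function of one variable
    forest = RandomForestRegressor(n_estimators=60, random_state=0).fit(X, y)
    imp = permutation_importance(forest, X, y, seed=0)
    assert np.argmax(imp) == 1
    assert imp[1] > 3 * max(abs(imp[j]) for j in (0, 2, 3))


def test_constant_variable_zero_with_warning():
    rng = np.random.default_rng(2)
    n = 40
    X = rng.normal(size=(n, 3))
    X[:, 2] = 1.0
    y = X[:, 0] + rng.normal(0, 0.1, n)
    forest = RandomForestRegressor(n_estimators=20, random_state=0).fit(X, y)
    with pytest.warns(UserWarning, match="constant"):
        imp = permutation_importance(forest, X, y, seed=0)
    assert imp[2] == 0.0


def test_oob_indices_complement_bootstrap():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(25, 2))
    y = rng.normal(size=25)
    forest = RandomForestRegressor(n_estimators=5, random_state=1).fit(X, y)
    for tree in forest.estimators_:
        oob = tree_oob_indices(tree, 25)
        sampled = np.random.RandomState(tree.random_state).randint(0, 25, 25)
        assert set(oob) == set(range(25)) - set(sampled.tolist())


def _ranking_data(seed=0, n=60, n_regions=6):
    rng = np.random.default_rng(seed)
    regions = [f"reg_{chr(97 + i)}" for i in range(n_regions)]
    data = pd.DataFrame(rng.normal(size=(n, n_regions)), columns=regions)
    data["age"] = rng.uniform(20, 70, n)
    data["sex"] = rng.integers(0, 2, n).astype(float)
    data["education"] = rng.normal(14, 2, n)
    data["visit_count"] = rng.choice([1.0, 3.0], n)
    data["y"] = 2 * data["reg_a"] + data["reg_b"] + rng.normal(0, 0.5, n)
    return data, regions


COVS = ["age", "sex", "education", "visit_count"]


def test_rank_variables_deterministic_and_conserving():
    data, regions = _ranking_data()
    cfg = ForestConfig(n_bootstrap_trees=30, n_repetitions=3, seed=9)
    r1 = rank_variables(data, "y", regions, COVS, cfg)
    r2 = rank_variables(data, "y", regions, COVS, cfg)
    pd.testing.assert_series_equal(r1.mean_rank, r2.mean_rank)
    pd.testing.assert_series_equal(r1.mean_importance, r2.mean_importance)
    # per-repetition midranks sum to m(m+1)/2, so their mean averages (m+1)/2
    m = len(regions)
    assert r1.mean_rank.mean() == pytest.approx((m + 1) / 2)
    assert sorted(r1.ordered_variables) == sorted(regions)
    # signal variables rank on top
    assert set(r1.ordered_variables[:2]) == {"reg_a", "reg_b"}


def test_ranking_invariant_to_column_order():
    data, regions = _ranking_data(seed=4)
    cfg = ForestConfig(n_bootstrap_trees=25, n_repetitions=2, seed=5)
    r1 = rank_variables(data, "y", regions, COVS, cfg)
    shuffled = list(reversed(regions))
    data2 = data[shuffled + COVS + ["y"]]
    r2 = rank_variables(data2, "y", shuffled, COVS, cfg)
    pd.testing.assert_series_equal(r1.mean_rank, r2.mean_rank)
    assert r1.ordered_variables == r2.ordered_variables


def test_duplicated_predictors_share_rank():
    """Identical columns split credit stochastically; their mean ranks agree
    within the between-repetition rank spread."""
    data, regions = _ranking_data(seed=6, n=80)
    data["reg_dup"] = data["reg_a"]
    cfg = ForestConfig(n_bootstrap_trees=40, n_repetitions=10, seed=2)
    r = rank_variables(data, "y", regions + ["reg_dup"], COVS, cfg)
    gap = abs(r.mean_rank["reg_a"] - r.mean_rank["reg_dup"])
    spread = max(r.rank_sd["reg_a"], r.rank_sd["reg_dup"], 0.5)
    assert gap <= spread


def test_rank_variables_validates_inputs():
    data, regions = _ranking_data()
    cfg = ForestConfig(n_bootstrap_trees=5, n_repetitions=1, seed=0)
    with pytest.raises(Exception, match="empty"):
        rank_variables(data, "y", [], COVS, cfg)
    with pytest.raises(Exception, match="30"):
        rank_variables(data.head(10), "y", regions, COVS, cfg)
    with pytest.raises(Exception, match="missing"):
        rank_variables(data, "y", regions + ["nope"], COVS, cfg)


@pytest.mark.parametrize("p, expected", [(1, 1), (3, 1), (9, 3), (44, 14)])
def test_mtry_rule(p, expected):
    assert mtry(p) == expected


def test_mean_rank_improves_with_signal_strength():
    """A region's mean rank is non-worsening (in expectation) as its signal
    coefficient grows; checked at three grid points."""
    ranks = []
    for coef in (0.0, 1.0, 3.0):
        vals = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(100 + seed)
            n = 70
            data = pd.DataFrame(
                rng.normal(size=(n, 5)), columns=[f"reg_{i}" for i in range(5)]
            )
            data["y"] = (
                coef * data["reg_0"] + data["reg_1"] + rng.normal(0, 0.5, n)
            )
            cfg = ForestConfig(n_bootstrap_trees=25, n_repetitions=4, seed=seed)
            r = rank_variables(
                data, "y", [f"reg_{i}" for i in range(5)], [], cfg
            )
            vals.append(r.mean_rank["reg_0"])
        ranks.append(np.mean(vals))
    assert ranks[1] <= ranks[0] and ranks[2] <= ranks[1]
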