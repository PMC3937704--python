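"""Normative forests: constant response, nonlinear recovery, residual logic."""

import numpy as np
import pandas as pd
import pytest

from morphocog.data_model import (
    Group,
    MorphometryTable,
    SampleSizeError,
    Sex,
    SubjectRecord,
    ValidationError,
)
from morphocog.normative import fit_normative, predict_normative, residualize
from morphocog.synthetic import SimulationConfig, simulate_cohort


def _make_controls(n, ages, region_values, seed_sex=0):
    rng = np.random.default_rng(seed_sex)
    sexes = [Sex.FEMALE if u < 0.5 else Sex.MALE for u in rng.random(n)]
    subjects = [
        SubjectRecord(
            subject_id=f"c{i}",
            group=Group.CONTROL,
            age=float(ages[i]),
            sex=sexes[i],
            education=14.0,
            visit_count=1,
        )
        for i in range(n)
    ]
    values = pd.DataFrame(
        {"ctx_a": region_values}, index=[s.subject_id for s in subjects]
    )
    morph = MorphometryTable(
        values=values,
        kinds=pd.Series({"ctx_a": "thickness"}),
        icv=pd.Series(1.5e6, index=values.index),
    )
    return subjects, morph


def test_constant_response_predicts_constant():
    n = 25
    subjects, morph = _make_controls(n, np.linspace(20, 70, n), np.full(n, 2.5))
    model = fit_normative(subjects, morph, n_trees=50, seed=0)
    frame = pd.DataFrame(
        {"age": [18.0, 80.0], "sex": ["female", "male"]}, index=["x", "y"]
    )
    pred = predict_normative(model, frame)
    np.testing.assert_allclose(pred["ctx_a"], 2.5)


def test_recovers_quadratic_age_effect():
    """With a noiseless quadratic age effect and n=500 the control OOB R^2
    exceeds 0.9 (oracle: the generative curve explains all variance; a
    piecewise-constant ensemble on 500 points approximates it closely)."""
    n = 500
    rng = np.random.default_rng(1)
    ages = rng.uniform(20, 70, n)
    values = 3.0 - 0.0004 * (ages - 20) ** 2
    subjects, morph = _make_controls(n, ages, values)
    model = fit_normative(subjects, morph, n_trees=200, seed=0)
    assert model.oob_r2["ctx_a"] >= 0.9


def test_refuses_small_or_mixed_samples():
    n = 10
    subjects, morph = _make_controls(n, np.linspace(20, 70, n), np.full(n, 2.5))
    with pytest.raises(SampleSizeError):
        fit_normative(subjects, morph, n_trees=10, seed=0)
    bad = [
        SubjectRecord(
            subject_id="k0",
            group=Group.CASE,
            age=40.0,
            sex=Sex.FEMALE,
            education=12.0,
            visit_count=1,
        )
    ]
    n = 25
    subjects, morph = _make_controls(n, np.linspace(20, 70, n), np.full(n, 2.5))
    with pytest.raises(ValidationError, match="control"):
        fit_normative(subjects + bad, morph, n_trees=10, seed=0)


def test_determinism_same_seed():
    n = 60
    rng = np.random.default_rng(2)
    ages = rng.uniform(20, 70, n)
    values = 2.8 - 0.003 * ages + rng.normal(0, 0.1, n)
    subjects, morph = _make_controls(n, ages, values)
    m1 = fit_normative(subjects, morph, n_trees=50, seed=5)
    m2 = fit_normative(subjects, morph, n_trees=50, seed=5)
    r1 = residualize(m1, subjects, morph)
    r2 = residualize(m2, subjects, morph)
    pd.testing.assert_frame_equal(r1.residuals, r2.residuals)


def test_zero_residuals_when_observed_equals_predicted():
    n = 30
    subjects, morph = _make_controls(n, np.linspace(20, 70, n), np.full(n, 2.5))
    model = fit_normative(subjects, morph, n_trees=50, seed=0)
    res = residualize(model, subjects, morph)
    np.testing.assert_allclose(res.residuals["ctx_a"], 0.0, atol=1e-12)


def test_in_sample_residuals_shrunken_relative_to_oob():
    """In-sample forest predictions track the training data too closely, so
    in-sample control residuals are biased toward zero; this motivates the
    out-of-bag default."""
    n = 120
    rng = np.random.default_rng(3)
    ages = rng.uniform(20, 70, n)
    values = 2.8 - 0.004 * ages + rng.normal(0, 0.15, n)
    subjects, morph = _make_controls(n, ages, values)
    oob = fit_normative(subjects, morph, n_trees=100, seed=1, prediction_mode="oob")
    ins = fit_normative(
        subjects, morph, n_trees=100, seed=1, prediction_mode="in_sample"
    )
    r_oob = residualize(oob, subjects, morph).residuals["ctx_a"].abs().mean()
    r_ins = residualize(ins, subjects, morph).residuals["ctx_a"].abs().mean()
    assert r_ins < r_oob


def test_case_residuals_capture_atrophy(small_cohort):
    """Cases generated with atrophy have lower mean residuals than controls
    in the atrophied regions (the screening decision direction)."""
    cfg, (subjects, morph, cognition, truth) = small_cohort
    controls = [s for s in subjects if s.group == Group.CONTROL]
    cases = [s for s in subjects if s.group == Group.CASE]
    model = fit_normative(controls, morph, n_trees=100, seed=0)
    res1 = residualize(model, controls, morph)
    res2 = residualize(model, cases, morph)
    for region in truth.atrophy_region_names:
        assert res2.residuals[region].mean() < res1.residuals[region].mean()
    # control OOB residuals are centred near zero
    null_regions = [
        r for r in morph.region_names if r not in truth.atrophy_region_names
    ]
    pooled = res1.residuals[null_regions].to_numpy().ravel()
    se = pooled.std(ddof=1) / np.sqrt(pooled.size)
    assert abs(pooled.mean()) < 4 * se


def test_extrapolation_warns_mixed_rejected():
    n = 30
    subjects, morph = _make_controls(n, np.linspace(30, 50, n), np.full(n, 2.5))
    model = fit_normative(subjects, morph, n_trees=20, seed=0)
    young = [
        SubjectRecord(
            subject_id="y0",
            group=Group.CASE,
            age=18.0,
            sex=Sex.FEMALE,
            education=12.0,
            visit_count=1,
        ),
        SubjectRecord(
            subject_id="y1",
            group=Group.CASE,
            age=75.0,
            sex=Sex.MALE,
            education=12.0,
            visit_count=1,
        ),
    ]
    values = pd.DataFrame({"ctx_a": [2.4, 2.6]}, index=["y0", "y1"])
    ymorph = MorphometryTable(
        values=values,
        kinds=pd.Series({"ctx_a": "thickness"}),
        icv=pd.Series(1.5e6, index=values.index),
    )
    with pytest.warns(UserWarning, match="age range"):
        residualize(model, young, ymorph)
    with pytest.raises(ValidationError, match="disjoint"):
        residualize(model, subjects[:5] + young, ymorph)
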