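"""Normative covariate adjustment of morphometry by random-forest regression.

Age and sex effects on each region are learned from the control group only
(one univariate forest per region, predictors exactly {age, sex}); trees
capture the nonlinear age trend and any age-by-sex interaction without an
explicit functional form.  Both groups are then residualized against the
control-derived norm: the control residuals form the reference distribution
and the case residuals carry any disease signal on top of it.

For the training (control) group the default prediction is out-of-bag:
in-sample forest predictions are strongly shrunken toward the observations,
which would bias control residuals toward zero and inflate apparent group
differences.  ``in_sample`` mode is retained for comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .importance import MIN_SAMPLES_LEAF
from .data_model import (
    Group,
    MorphometryTable,
    ResidualTable,
    SampleSizeError,
    Sex,
    SubjectRecord,
    ValidationError,
    subjects_to_frame,
)

logger = logging.getLogger(__name__)

#: Years beyond the training age range before an extrapolation warning fires.
EXTRAPOLATION_GUARD_YEARS = 10.0


def _design(frame: pd.DataFrame) -> np.ndarray:
    """Predictor matrix [age, male01]."""
    male = (frame["sex"] == Sex.MALE.value).astype(float)
    return np.column_stack([frame["age"].to_numpy(dtype=float), male.to_numpy()])


@dataclass
class NormativeModel:
    forests: dict[str, RandomForestRegressor]
    training_ids: list[str]
    training_age_range: tuple[float, float]
    prediction_mode: str
    n_trees: int
    seed: int
    oob_r2: dict[str, float] = field(default_factory=dict)
    _oob_predictions: pd.DataFrame | None = None

    @property
    def region_names(self) -> list[str]:
        return list(self.forests)


def fit_normative(
    subjects: Sequence[SubjectRecord],
    morphometry: MorphometryTable,
    n_trees: int = 500,
    seed: int = 0,
    prediction_mode: str = "oob",
) -> NormativeModel:
    """Fit one forest per region on control subjects with predictors {age, sex}."""
    if prediction_mode not in ("oob", "in_sample"):
        raise ValidationError(f"unknown prediction_mode {prediction_mode!r}")
    frame = subjects_to_frame(subjects)
    controls = frame[frame["group"] == Group.CONTROL.value]
    if len(controls) < len(frame):
        raise ValidationError("fit_normative accepts control subjects only")
    if len(controls) < 20:
        raise SampleSizeError(
            f"normative fit needs >= 20 controls, got {len(controls)}"
        )
    morph = morphometry.restrict(list(controls.index))
    X = _design(controls)

    forests: dict[str, RandomForestRegressor] = {}
    oob_r2: dict[str, float] = {}
    oob_pred = {}
    seeds = np.random.SeedSequence(seed).generate_state(len(morph.region_names))
    for rs, region in zip(seeds, morph.region_names):
        y = morph.values[region].to_numpy(dtype=float)
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            oob_score=True,
            min_samples_leaf=MIN_SAMPLES_LEAF,
            random_state=int(rs % (2**31)),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            # constant-response regions yield an undefined OOB R^2
            warnings.simplefilter("ignore", UserWarning)
            forest.fit(X, y)
        forests[region] = forest
        oob_pred[region] = forest.oob_prediction_
        var = float(np.var(y))
        oob_r2[region] = float(forest.oob_score_) if var > 0 else float("nan")

    return NormativeModel(
        forests=forests,
        training_ids=list(controls.index),
        training_age_range=(
            float(controls["age"].min()),
            float(controls["age"].max()),
        ),
        prediction_mode=prediction_mode,
        n_trees=n_trees,
        seed=seed,
        oob_r2=oob_r2,
        _oob_predictions=pd.DataFrame(oob_pred, index=list(controls.index)),
    )


def predict_normative(
    model: NormativeModel, subjects_frame: pd.DataFrame
) -> pd.DataFrame:
    """Full-forest predictions for arbitrary subjects (age/sex only)."""
    X = _design(subjects_frame)
    preds = {
        region: forest.predict(X) for region, forest in model.forests.items()
    }
    return pd.DataFrame(preds, index=subjects_frame.index)


def residualize(
    model: NormativeModel,
    subjects: Sequence[SubjectRecord],
    morphometry: MorphometryTable,
) -> ResidualTable:
    """Observed minus normative-predicted morphometry.

    The subject set must either coincide with the training controls (then the
    model's configured prediction mode applies) or be disjoint from it (cases:
    full-forest predictions).  Mixed sets are rejected because the two halves
    would carry incomparable residual distributions.
    """
    frame = subjects_to_frame(subjects)
    ids = set(frame.index)
    train = set(model.training_ids)
    if ids == train:
        if model.prediction_mode == "oob":
            predicted = model._oob_predictions.loc[list(frame.index)]
        else:
            predicted = predict_normative(model, frame)
    elif ids.isdisjoint(train):
        lo, hi = model.training_age_range
        out = (
            (frame["age"] < lo - EXTRAPOLATION_GUARD_YEARS)
            | (frame["age"] > hi + EXTRAPOLATION_GUARD_YEARS)
        )
        if out.any():
            warnings.warn(
                f"{int(out.sum())} subject(s) outside the normative age range "
                f"[{lo:.1f}, {hi:.1f}] +/- {EXTRAPOLATION_GUARD_YEARS:.0f} y; "
                "predictions are extrapolations",
                UserWarning,
                stacklevel=2,
            )
        predicted = predict_normative(model, frame)
    else:
        raise ValidationError(
            "residualize: subject set must be identical to or disjoint from "
            "the training controls"
        )
    morph = morphometry.restrict(list(frame.index))
    residuals = morph.values[model.region_names] - predicted[model.region_names]
    return ResidualTable(
        residuals=residuals, group_labels=frame["group"].astype(str)
    )


def residualize_cohort(
    model: NormativeModel,
    subjects: Sequence[SubjectRecord],
    morphometry: MorphometryTable,
) -> ResidualTable:
    """Residualize controls (training mode) and cases (full forest) and stack
    them into one table in cohort order."""
    frame = subjects_to_frame(subjects)
    ctrl = [s for s in subjects if s.group == Group.CONTROL]
    case = [s for s in subjects if s.group == Group.CASE]
    parts = []
    if ctrl:
        parts.append(residualize(model, ctrl, morphometry))
    if case:
        parts.append(residualize(model, case, morphometry))
    residuals = pd.concat([p.residuals for p in parts]).loc[frame.index]
    labels = pd.concat([p.group_labels for p in parts]).loc[frame.index]
    return ResidualTable(residuals=residuals, group_labels=labels)
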