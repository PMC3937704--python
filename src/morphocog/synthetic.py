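"""Synthetic two-group cohort generator with known ground truth.

Emulates a prodromal-Huntington-style case-control study: ~119 gene-negative
controls and ~325 carriers, 68 cortical thickness regions (34 per hemisphere,
Desikan-Killiany parcellation) plus bilateral caudate and putamen expressed
as volume/ICV ratios.  Morphometry carries a mildly nonlinear decreasing age
effect, a sex offset, a small age-by-sex interaction, block-correlated noise
(regions within a lobe co-vary), and — in cases only — atrophy in a known
region subset scaled by a per-subject disease-severity factor.  Cognitive
outcomes are driven by a known subset of the atrophied regions plus small
covariate effects, so every inference stage of the pipeline can be scored
against ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    COGNITIVE_OUTCOMES,
    CognitiveScores,
    Group,
    MorphometryTable,
    RegionKind,
    Sex,
    SubjectRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Desikan-Killiany gyral/sulcal parcels (34 per hemisphere).
DESIKAN_KILLIANY = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
)

#: Lobe assignment used for the block-correlation structure.
_LOBE = {
    "bankssts": "temporal", "caudalanteriorcingulate": "cingulate",
    "caudalmiddlefrontal": "frontal", "cuneus": "occipital",
    "entorhinal": "temporal", "frontalpole": "frontal", "fusiform": "temporal",
    "inferiorparietal": "parietal", "inferiortemporal": "temporal",
    "insula": "insula", "isthmuscingulate": "cingulate",
    "lateraloccipital": "occipital", "lateralorbitofrontal": "frontal",
    "lingual": "occipital", "medialorbitofrontal": "frontal",
    "middletemporal": "temporal", "paracentral": "frontal",
    "parahippocampal": "temporal", "parsopercularis": "frontal",
    "parsorbitalis": "frontal", "parstriangularis": "frontal",
    "pericalcarine": "occipital", "postcentral": "parietal",
    "posteriorcingulate": "cingulate", "precentral": "frontal",
    "precuneus": "parietal", "rostralanteriorcingulate": "cingulate",
    "rostralmiddlefrontal": "frontal", "superiorfrontal": "frontal",
    "superiorparietal": "parietal", "superiortemporal": "temporal",
    "supramarginal": "parietal", "temporalpole": "temporal",
    "transversetemporal": "temporal",
}

STRIATAL_REGIONS = ("lh_caudate", "rh_caudate", "lh_putamen", "rh_putamen")

# Measurement scale per region kind: thickness in mm, ratios ~2.5e-3, so one
# "unit" of ratio-scale noise is 0.002 of the thickness scale.
_RATIO_SCALE = 0.002
_THICKNESS_FLOOR = 0.5
_RATIO_FLOOR = 1e-5


def default_region_names(n_regions: int) -> list[str]:
    """72-region default = bilateral Desikan-Killiany + bilateral caudate/putamen;
    other sizes get generic cortical names, with 4 striatal regions appended
    whenever n_regions >= 16."""
    if n_regions == 72:
        cortical = [f"{h}_{r}" for h in ("lh", "rh") for r in DESIKAN_KILLIANY]
        return cortical + list(STRIATAL_REGIONS)
    if n_regions >= 16:
        cortical = [f"ctx_{i:03d}" for i in range(n_regions - 4)]
        return cortical + list(STRIATAL_REGIONS)
    return [f"ctx_{i:03d}" for i in range(n_regions)]


def _region_blocks(names: Sequence[str]) -> np.ndarray:
    """Integer block label per region (hemisphere x lobe; striatum one block)."""
    labels = []
    for name in names:
        if name in STRIATAL_REGIONS:
            labels.append("striatum")
        elif name.startswith(("lh_", "rh_")):
            hemi, parc = name.split("_", 1)
            labels.append(f"{hemi}_{_LOBE.get(parc, 'other')}")
        else:
            # generic names: blocks of 8
            idx = int(name.split("_")[1])
            labels.append(f"block_{idx // 8}")
    uniq = {lab: i for i, lab in enumerate(dict.fromkeys(labels))}
    return np.array([uniq[lab] for lab in labels])


@dataclass
class SimulationConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_control: int = 119
    n_case: int = 325
    n_regions: int = 72
    atrophy_region_indices: frozenset[int] = field(default_factory=frozenset)
    atrophy_effect_sd: float = 0.5
    outcome_region_indices: frozenset[int] = field(default_factory=frozenset)
    outcome_model: str = "linear"  # linear | nonlinear | interaction
    noise_sd: float = 0.12
    age_range: tuple[float, float] = (18.0, 75.0)
    seed: int = 0
    block_rho: float = 0.4
    outcome_r2: float = 0.6
    severity_shape: float = 2.0
    severity_scale: float = 0.5

    def __post_init__(self) -> None:
        self.atrophy_region_indices = frozenset(self.atrophy_region_indices)
        self.outcome_region_indices = frozenset(self.outcome_region_indices)
        if self.n_control < 10 or self.n_case < 10:
            raise ValidationError("need at least 10 subjects per group")
        if not self.atrophy_region_indices <= set(range(self.n_regions)):
            raise ValidationError("atrophy_region_indices outside region range")
        if not self.outcome_region_indices <= self.atrophy_region_indices:
            # outcome-relevant regions must survive the atrophy screen to be
            # discoverable by the second stage
            if self.outcome_region_indices and not self.atrophy_region_indices:
                raise ValidationError(
                    "nonempty outcome set requires a nonempty atrophy set"
                )
            raise ValidationError(
                "outcome_region_indices must be a subset of atrophy_region_indices"
            )
        if self.outcome_model not in ("linear", "nonlinear", "interaction"):
            raise ValidationError(f"unknown outcome_model {self.outcome_model!r}")
        if not (0 <= self.block_rho < 1):
            raise ValidationError("block_rho must be in [0, 1)")
        if not (0 < self.outcome_r2 < 1):
            raise ValidationError("outcome_r2 must be in (0, 1)")


def study_default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Config mirroring the emulated study's structure: 40 atrophied regions
    (bilateral caudate/putamen + 36 cortical) with 5 of them driving the
    cognitive outcomes (both putamina + 3 cortical)."""
    names = default_region_names(72)
    cortical_atrophied = [
        f"{h}_{r}"
        for h in ("lh", "rh")
        for r in (
            "caudalmiddlefrontal", "superiorfrontal", "precentral", "paracentral",
            "parsopercularis", "superiortemporal", "middletemporal", "bankssts",
            "superiorparietal", "inferiorparietal", "supramarginal", "precuneus",
            "postcentral", "lateraloccipital", "lingual", "cuneus",
            "pericalcarine", "isthmuscingulate",
        )
    ]
    atrophied = [names.index(n) for n in cortical_atrophied] + [
        names.index(n) for n in STRIATAL_REGIONS
    ]
    outcome = [
        names.index(n)
        for n in (
            "lh_putamen", "rh_putamen", "lh_caudalmiddlefrontal",
            "rh_superiortemporal", "lh_superiorparietal",
        )
    ]
    cfg = dict(
        atrophy_region_indices=frozenset(atrophied),
        outcome_region_indices=frozenset(outcome),
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


@dataclass
class GroundTruth:
    """Generative truth stored alongside a simulated cohort for scoring."""

    atrophy_region_indices: list[int]
    atrophy_region_names: list[str]
    outcome_region_indices: dict[str, list[int]]
    outcome_region_names: dict[str, list[str]]
    outcome_weights: dict[str, list[float]]
    covariate_coefficients: dict[str, float]
    n_floored: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def severity_profile(
    n_case: int, seed: int, shape: float = 2.0, scale: float = 0.5
) -> np.ndarray:
    """Per-case positive disease-burden multipliers, gamma-distributed with
    mean ``shape * scale`` (defaults give mean 1, right-skewed), so the
    configured atrophy effect is the mean group shift."""
    if n_case < 1:
        raise ValidationError("n_case must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.gamma(shape=shape, scale=scale, size=n_case)


# outcome measurement scales: (mean, sd) on the reported score scale
_OUTCOME_SCALE = {
    "sdmt": (50.0, 10.0),
    "letter_number": (11.0, 3.0),
    "hvlt_immediate": (26.0, 4.0),
    "negative_emotions": (20.0, 4.0),
    "timing_precision": (0.02, 0.25),  # lognormal: exp-scale sigma
}


def _region_signal(z: np.ndarray, w: np.ndarray, model: str, rng: np.random.Generator) -> np.ndarray:
    if model == "linear":
        return z @ w
    if model == "nonlinear":
        # monotone-in-each-region but saturating contribution
        return (z + 0.6 * np.tanh(z)) @ w
    # interaction: pairwise product of the two heaviest regions on top of the
    # linear part
    s = z @ w
    if z.shape[1] >= 2:
        top = np.argsort(w)[-2:]
        s = s + 0.6 * z[:, top[0]] * z[:, top[1]]
    return s


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SubjectRecord], MorphometryTable, CognitiveScores, GroundTruth]:
    """Generate one cohort.

    Morphometry model per region r and subject i::

        value = baseline_r + f_age(age_i) + g_sex + h(age_i, sex_i)
                - atrophy * noise_sd_r * severity_i * 1[case, r in atrophy set]
                + eps_ir

    with f_age monotone decreasing and mildly quadratic, eps block-correlated
    Gaussian noise of SD ``noise_sd`` (thickness scale).  Outcomes are a
    linear / saturating / interacting function of the outcome regions plus
    small covariate effects plus Gaussian noise sized to leave fraction
    ``outcome_r2`` of latent variance to the region signal.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_control + config.n_case
    names = default_region_names(config.n_regions)
    is_case = np.concatenate(
        [np.zeros(config.n_control, bool), np.ones(config.n_case, bool)]
    )

    # --- demographics -----------------------------------------------------
    age = rng.uniform(*config.age_range, size=n)
    female = rng.random(n) < 0.65
    education = np.clip(rng.normal(14.0, 2.8, size=n), 8.0, 20.0)
    visit_count = rng.choice([1, 3], size=n)
    cag = np.where(is_case, rng.integers(38, 51, size=n), 0)
    motor = np.clip(rng.normal(np.where(is_case, 5.0, 1.0), 2.0), 0.0, None)

    severity = rng.gamma(
        shape=config.severity_shape, scale=config.severity_scale, size=config.n_case
    )
    sev_all = np.zeros(n)
    sev_all[is_case] = severity

    # --- morphometry ------------------------------------------------------
    kinds = {
        name: (
            RegionKind.VOLUME_RATIO.value
            if name in STRIATAL_REGIONS
            else RegionKind.THICKNESS.value
        )
        for name in names
    }
    scale = np.array(
        [_RATIO_SCALE if name in STRIATAL_REGIONS else 1.0 for name in names]
    )
    baseline = np.array(
        [
            (0.0024 if "caudate" in name else 0.0030)
            if name in STRIATAL_REGIONS
            else rng.uniform(2.0, 3.2)
            for name in names
        ]
    )

    age_c = age - 40.0
    male = (~female).astype(float)
    f_age = -(0.004 * age_c + 3.0e-5 * age_c**2)  # monotone decreasing on [18, 75]
    g_sex = -0.06 * male
    h_int = 0.0015 * age_c * male
    covar_effect = f_age + g_sex + h_int  # thickness scale; multiplied by `scale`

    blocks = _region_blocks(names)
    z_block = rng.standard_normal((n, blocks.max() + 1))
    z_ind = rng.standard_normal((n, config.n_regions))
    rho = config.block_rho
    eps = np.sqrt(rho) * z_block[:, blocks] + np.sqrt(1 - rho) * z_ind

    atrophy_idx = sorted(config.atrophy_region_indices)
    atrophy_mask = np.zeros(config.n_regions)
    atrophy_mask[atrophy_idx] = 1.0

    values = (
        baseline[None, :]
        + covar_effect[:, None] * scale[None, :]
        + eps * config.noise_sd * scale[None, :]
        - (
            config.atrophy_effect_sd
            * config.noise_sd
            * sev_all[:, None]
            * atrophy_mask[None, :]
            * scale[None, :]
        )
    )

    floor = np.array(
        [_RATIO_FLOOR if name in STRIATAL_REGIONS else _THICKNESS_FLOOR for name in names]
    )
    n_floored = int((values < floor[None, :]).sum())
    if n_floored:
        logger.info("floored %d generated value(s) at the positivity bound", n_floored)
    values = np.maximum(values, floor[None, :])
    # keep ratios inside (0, 1)
    ratio_cols = [i for i, name in enumerate(names) if name in STRIATAL_REGIONS]
    values[:, ratio_cols] = np.minimum(values[:, ratio_cols], 0.5)

    icv = rng.normal(1.5e6, 1.2e5, size=n) + 8.0e4 * male
    subject_ids = [f"S{i:04d}" for i in range(n)]
    values_df = pd.DataFrame(values, index=subject_ids, columns=names)
    morph = MorphometryTable(
        values=values_df,
        kinds=pd.Series(kinds),
        icv=pd.Series(icv, index=subject_ids),
    )

    # --- cognitive outcomes ----------------------------------------------
    outcome_idx = sorted(config.outcome_region_indices)
    z_age = (age - np.mean(config.age_range)) / (
        (config.age_range[1] - config.age_range[0]) / np.sqrt(12)
    )
    z_edu = (education - 14.0) / 2.8
    cov_coef = {"age": -0.15, "education": 0.10, "male": -0.05, "visit3": 0.05}
    cov_part = (
        cov_coef["age"] * z_age
        + cov_coef["education"] * z_edu
        + cov_coef["male"] * male
        + cov_coef["visit3"] * (visit_count == 3)
    )

    cog = {}
    truth_weights: dict[str, list[float]] = {}
    for outcome in COGNITIVE_OUTCOMES:
        if outcome_idx:
            sub = values[:, outcome_idx]
            z = (sub - sub.mean(axis=0)) / np.where(sub.std(axis=0) > 0, sub.std(axis=0), 1.0)
            w = rng.uniform(0.7, 1.0, size=len(outcome_idx))
            s = _region_signal(z, w, config.outcome_model, rng)
            sd_s = s.std() if s.std() > 0 else 1.0
            noise_scale = sd_s * np.sqrt((1 - config.outcome_r2) / config.outcome_r2)
            latent = s + cov_part * sd_s + rng.normal(0.0, noise_scale, size=n)
            truth_weights[outcome] = [float(x) for x in w]
        else:
            latent = cov_part + rng.standard_normal(n)
            truth_weights[outcome] = []
        latent = (latent - latent.mean()) / (latent.std() if latent.std() > 0 else 1.0)
        mu, sd = _OUTCOME_SCALE[outcome]
        if outcome == "timing_precision":
            cog[outcome] = mu * np.exp(sd * latent)
        else:
            cog[outcome] = np.clip(np.round(mu + sd * latent), 0, None)

    cognition = CognitiveScores(
        values=pd.DataFrame(cog, index=subject_ids)[list(COGNITIVE_OUTCOMES)]
    )

    subjects = [
        SubjectRecord(
            subject_id=subject_ids[i],
            group=Group.CASE if is_case[i] else Group.CONTROL,
            age=float(age[i]),
            sex=Sex.FEMALE if female[i] else Sex.MALE,
            education=float(education[i]),
            visit_count=int(visit_count[i]),
            cag_repeats=int(cag[i]) if is_case[i] else None,
            motor_score=float(motor[i]),
        )
        for i in range(n)
    ]

    truth = GroundTruth(
        atrophy_region_indices=list(atrophy_idx),
        atrophy_region_names=[names[i] for i in atrophy_idx],
        outcome_region_indices={o: list(outcome_idx) for o in COGNITIVE_OUTCOMES},
        outcome_region_names={
            o: [names[i] for i in outcome_idx] for o in COGNITIVE_OUTCOMES
        },
        outcome_weights=truth_weights,
        covariate_coefficients=cov_coef,
        n_floored=n_floored,
    )
    return subjects, morph, cognition, truth
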