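"""End-to-end pipeline orchestration with reproducibility metadata.

Stage order: simulate (or load) -> compare (covariate-adjusted group tests)
-> normative (control-trained residualization) -> screen (FDR atrophy
screen) -> rank (repeated permutation-importance ranking, cases only) ->
select (top-k OOB-MSE curve and parsimony choice).  Each stage writes its
outputs (CSV tables + JSON metadata) before the next begins, and every run
records seed, configuration hash and package version so it can be
reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cognitive import ancova_group_test, group_summary, visit_effect_check
from .data_model import (
    COGNITIVE_OUTCOMES,
    COVARIATES,
    Group,
    Sex,
    complete_case_mask,
    read_cohort,
    subjects_to_frame,
    write_cohort,
)
from .importance import ForestConfig, rank_variables
from .normative import fit_normative, residualize_cohort
from .screening import screen_regions
from .selection import build_curve, choose_k, report_selected
from .synthetic import SimulationConfig, simulate_cohort, study_default_config

logger = logging.getLogger(__name__)

STAGES = ("simulate", "compare", "normative", "screen", "rank", "select")


class PipelineHalt(RuntimeError):
    """The pipeline cannot proceed (e.g. empty predictor set)."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    out_dir: str = "run"
    seed: int = 0
    # input cohort; None -> simulate
    subjects_path: Optional[str] = None
    morphometry_path: Optional[str] = None
    cognition_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    alpha: float = 0.05
    parsimony_rule: str = "one_se"
    outcomes: tuple[str, ...] = COGNITIVE_OUTCOMES
    scale: str = "reduced"  # reduced | full
    normative_trees: int = 200
    rank_trees: int = 300
    rank_repetitions: int = 25
    selection_runs: int = 20
    selection_trees: int = 150
    max_k: Optional[int] = 20
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.scale == "full":
            self.normative_trees = 500
            self.rank_trees = 5000
            self.rank_repetitions = 1000
            self.selection_runs = 200
            self.selection_trees = 5000
            self.max_k = None
        elif self.scale != "reduced":
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "reduced":
            logger.info(
                "reduced-scale run: %d/%d/%d trees/repetitions/runs "
                "(full scale: 5000/1000/200)",
                self.rank_trees,
                self.rank_repetitions,
                self.selection_runs,
            )

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        if self.simulation is not None:
            payload["simulation"] = dataclasses.asdict(self.simulation)
            for key in ("atrophy_region_indices", "outcome_region_indices"):
                payload["simulation"][key] = sorted(payload["simulation"][key])
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _covariate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate matrix (sex as male indicator)."""
    return pd.DataFrame(
        {
            "age": frame["age"].astype(float),
            "sex": (frame["sex"] == Sex.MALE.value).astype(float),
            "education": frame["education"].astype(float),
            "visit_count": frame["visit_count"].astype(float),
        },
        index=frame.index,
    )


def run_pipeline(
    config: RunConfig, until: str = "select"
) -> dict:
    """Execute the pipeline up to (and including) stage ``until``.

    Returns a summary dict (also written to ``summary.json``); raises
    :class:`PipelineHalt` if screening selects no region.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    last = STAGES.index(until)
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "scale": config.scale,
        "stages_run": [],
    }

    # --- simulate / load --------------------------------------------------
    if config.subjects_path is not None:
        subjects, morph, cognition = read_cohort(
            config.subjects_path, config.morphometry_path, config.cognition_path
        )
        truth = None
    else:
        sim = config.simulation or study_default_config(seed=config.seed)
        subjects, morph, cognition, truth = simulate_cohort(sim)
        write_cohort(
            out,
            subjects,
            morph,
            cognition,
            metadata={"seed": sim.seed, "config_hash": config.config_hash()},
        )
        truth.to_json(out / "ground_truth.json")
    summary["n_subjects"] = len(subjects)
    summary["stages_run"].append("simulate")
    if last == STAGES.index("simulate"):
        return _finish(out, summary)

    frame = subjects_to_frame(subjects)
    mask = complete_case_mask(frame)
    frame = frame[mask]
    subjects = [s for s in subjects if mask[s.subject_id]]
    covs = _covariate_frame(frame)

    # --- compare ----------------------------------------------------------
    if STAGES.index("compare") <= last:
        rows = []
        for outcome in config.outcomes:
            y = cognition.values.loc[frame.index, outcome]
            keep = y.notna()
            res = ancova_group_test(
                y[keep].to_numpy(),
                frame.loc[keep, "group"],
                covs.loc[keep],
                outcome_name=outcome,
            )
            rows.append(
                {
                    "outcome": outcome,
                    "effect": res.effect,
                    "t": res.t_statistic,
                    "p": res.p_value,
                }
            )
            visit = visit_effect_check(
                y[keep].to_numpy(),
                frame.loc[keep, "group"],
                frame.loc[keep, "visit_count"].to_numpy(),
                covs.loc[keep, ["age", "sex", "education"]],
            )
            if visit is not None:
                rows[-1]["p_visit"] = visit.p_visit
                rows[-1]["p_visit_x_group"] = visit.p_interaction
        pd.DataFrame(rows).to_csv(out / "group_comparison.csv", index=False)
        group_summary(
            cognition.values.loc[frame.index], frame["group"]
        ).to_csv(out / "group_means.csv", index=False)
        summary["stages_run"].append("compare")
    if last == STAGES.index("compare"):
        return _finish(out, summary)

    # --- normative --------------------------------------------------------
    controls = [s for s in subjects if s.group == Group.CONTROL]
    model = fit_normative(
        controls,
        morph,
        n_trees=config.normative_trees,
        seed=config.seed,
    )
    residuals = residualize_cohort(model, subjects, morph)
    residuals.residuals.to_csv(out / "residuals.csv")
    (out / "normative_meta.json").write_text(
        json.dumps(
            {
                "prediction_mode": model.prediction_mode,
                "n_trees": model.n_trees,
                "seed": model.seed,
                "oob_r2": model.oob_r2,
            },
            indent=2,
            sort_keys=True,
        )
    )
    summary["stages_run"].append("normative")
    if last == STAGES.index("normative"):
        return _finish(out, summary)

    # --- screen -----------------------------------------------------------
    results, predictor_set = screen_regions(residuals, alpha=config.alpha)
    pd.DataFrame(
        [
            {
                "region": r.region_name,
                "statistic": r.statistic,
                "p": r.p_value,
                "q": r.q_value,
                "significant": r.significant,
            }
            for r in results
        ]
    ).to_csv(out / "screening.csv", index=False)
    (out / "predictor_set.json").write_text(
        json.dumps({"alpha": config.alpha, "predictors": predictor_set}, indent=2)
    )
    summary["n_predictors"] = len(predictor_set)
    summary["stages_run"].append("screen")
    if not predictor_set:
        summary["halted"] = "empty predictor set after screening"
        _finish(out, summary)
        raise PipelineHalt("no region survived screening; cannot rank predictors")
    if last == STAGES.index("screen"):
        return _finish(out, summary)

    # --- rank + select (cases only) ---------------------------------------
    cases = frame[frame["group"] == Group.CASE.value]
    data = pd.concat(
        [
            morph.values.loc[cases.index, predictor_set],
            _covariate_frame(cases),
            cognition.values.loc[cases.index],
        ],
        axis=1,
    )
    selected_k = {}
    for outcome in config.outcomes:
        sub = data[data[outcome].notna()]
        fc = ForestConfig(
            n_bootstrap_trees=config.rank_trees,
            n_repetitions=config.rank_repetitions,
            seed=config.seed,
            n_jobs=config.n_jobs,
        )
        ranking = rank_variables(
            sub, outcome, predictor_set, list(COVARIATES), fc
        )
        ranking.to_frame().to_csv(out / f"importance_{outcome}.csv", index=False)
        if STAGES.index("select") <= last:
            curve = build_curve(
                sub,
                outcome,
                ranking,
                list(COVARIATES),
                n_runs=config.selection_runs,
                n_trees=config.selection_trees,
                seed=config.seed,
                max_k=config.max_k,
                n_jobs=config.n_jobs,
            )
            curve.to_frame().to_csv(out / f"curve_{outcome}.csv", index=False)
            k = choose_k(curve, config.parsimony_rule)
            report_selected(ranking, k, sub, outcome).to_csv(
                out / f"selected_{outcome}.csv", index=False
            )
            selected_k[outcome] = {"k_chosen": k, "k_min": curve.k_min}
    summary["stages_run"].append("rank")
    if STAGES.index("select") <= last:
        summary["stages_run"].append("select")
        summary["selected_k"] = selected_k
    return _finish(out, summary)


def _finish(out: Path, summary: dict) -> dict:
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
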