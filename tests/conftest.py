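import numpy as np
import pandas as pd
import pytest

from morphocog.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small default cohort with 6 atrophied regions, 3 driving outcomes."""
    cfg = SimulationConfig(
        n_control=60,
        n_case=90,
        n_regions=24,
        atrophy_region_indices=frozenset({0, 3, 7, 20, 21, 22}),
        outcome_region_indices=frozenset({0, 20, 21}),
        atrophy_effect_sd=0.8,
        outcome_r2=0.6,
        seed=11,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def cohort_frames(small_cohort):
    from morphocog.data_model import subjects_to_frame

    cfg, (subjects, morph, cognition, truth) = small_cohort
    return subjects_to_frame(subjects), morph, cognition, truth
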