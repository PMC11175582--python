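"""Shared fixtures: one small synthetic cohort reused across the suite.

Trajectory resolution is reduced (2 s at 50 Hz instead of 35 s at 133 Hz)
wherever the test does not concern the frame-count contract itself; kinematic
summaries are stationary in duration and rate, so nothing else depends on it.
"""

import numpy as np
import pandas as pd
import pytest

from mentakin import GeneratorParams, generate_cohort, tables
from mentakin.inference import SamplerSettings

#: Reduced sampling budget for test fits (walker-ensemble steps).
FAST = SamplerSettings(iterations_per_chain=900, warmup=300, thin=3)


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(12, seed=42, duration_s=2.0, rate_hz=50.0)


@pytest.fixture(scope="session")
def trial_tab(cohort):
    return tables.trial_table(cohort.animation_trials, cohort.subjects)


@pytest.fixture(scope="session")
def change_tab(cohort, trial_tab):
    return tables.change_table(trial_tab, cohort.emotion_trials, cohort.wm_trials)


@pytest.fixture(scope="session")
def walk_tab(cohort):
    return tables.walk_table(cohort.walk, cohort.subjects)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
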