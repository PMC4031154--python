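import dataclasses

import numpy as np
import pytest

from copsway.pipeline import evaluate_study
from copsway.synthetic import StudyDesign, simulate_study


@pytest.fixture(scope="session")
def default_design():
    return StudyDesign(seed=123)


@pytest.fixture(scope="session")
def default_sim(default_design):
    """One full-size synthetic cohort (the generator's default conditions)."""
    return simulate_study(default_design)


@pytest.fixture(scope="session")
def default_report(default_sim):
    return evaluate_study(default_sim.study, default_sim.subjects)


@pytest.fixture
def rng():
    return np.random.default_rng(99)


def small_design(**overrides) -> StudyDesign:
    """A fast cohort for unit tests: fewer subjects, short trials."""
    base = dict(
        n_subjects=6,
        sessions_per_subject=2,
        trial_duration=10.24,
        dropout_prob_ce=0.0,
        dropout_prob_cf=0.0,
        seed=7,
    )
    base.update(overrides)
    return StudyDesign(**base)


def random_trajectory(rng, n=400, rate=50.0, sd=5.0):
    from copsway.metrics import COPTrajectory

    t = np.arange(n) / rate
    return COPTrajectory(t=t, x=rng.normal(0, sd, n), y=rng.normal(0, sd, n))
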