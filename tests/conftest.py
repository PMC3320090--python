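import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mcistates as m

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def simple_norms() -> m.NormTable:
    """Two-test norms with known intercept/slope/SD for hand-checkable cut-offs."""
    table = pd.DataFrame(
        {
            "intercept": {"recall": 80.0, "errors": -2.0},
            "slope": {"recall": -0.5, "errors": 0.1},
            "sd": {"recall": 4.0, "errors": 2.0},
            "n": {"recall": 100, "errors": 100},
        }
    ).rename_axis("test")
    return m.NormTable(table)


@pytest.fixture(scope="session")
def simple_battery() -> dict:
    return {
        "recall": m.TestSpec("memory"),
        "errors": m.TestSpec("nonmemory", higher_is_worse=True),
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-subject simulated cohort with its transition pairs (sigma_u = 0.5)."""
    spec = m.CohortSpec(seed=7, n_subjects=120)
    trajs = m.simulate_cohort(spec)
    return spec, trajs, m.build_pairs(trajs)


def make_trajectory(states, subject_id=0, test_based=None, age=75.0):
    """Trajectory helper with annual visits and a complete covariate set."""
    states = [m.State[s] if isinstance(s, str) else m.State(s) for s in states]
    return m.Trajectory(
        subject_id=subject_id,
        times=np.arange(len(states), dtype=float),
        states=states,
        age_at_entry=age,
        covariates={"female": 1.0, "famhx": 0.0, "apoe4": 0.0, "low_educ": 0.0, "htn": 1.0},
        test_based=test_based,
    )
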