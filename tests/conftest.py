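import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vppgrf as v

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def subject():
    return v.SubjectParams(M=75.0, BH=1.75)


@pytest.fixture(scope="session")
def squat_trial():
    """Noiseless default squat: double support throughout."""
    return v.simulate_squat()


@pytest.fixture(scope="session")
def lunge_trial():
    return v.simulate_lunge()


@pytest.fixture(scope="session")
def walk_trial():
    return v.simulate_walk()


def max_rel_grf_error(sol, trial):
    """Worst per-frame relative error of predicted vs truth per-foot GRFs.

    The denominator floors at 1e-9·BW so unloaded (zero-truth) frames compare
    absolutely at a negligible scale.
    """
    worst = 0.0
    for pred, truth in ((sol.grf_l, trial.truth_grf_l), (sol.grf_r, trial.truth_grf_r)):
        den = np.maximum(np.linalg.norm(truth, axis=1), 1e-9 * trial.subject.BW)
        worst = max(worst, float((np.linalg.norm(pred - truth, axis=1) / den).max()))
    return worst
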