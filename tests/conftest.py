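import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gaitlds import GaitSimConfig, simulate_gait  # noqa: E402


@pytest.fixture(scope="session")
def short_walk():
    """A 60-stride turn-free walk with mild stride-to-stride jitter."""
    return simulate_gait(GaitSimConfig(seed=11, n_strides=60, turn_every=None,
                                       perturbation_sd=0.03))


@pytest.fixture(scope="session")
def default_walk():
    """The default 5-minute corridor protocol, turns included."""
    return simulate_gait(GaitSimConfig(seed=5))


@pytest.fixture(scope="session")
def study_cohort():
    from gaitlds import CohortSimConfig, simulate_cohort

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, truth = simulate_cohort(CohortSimConfig(seed=0))
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
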