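import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nfbtrain.protocol import build_protocol
from nfbtrain.simulate import simulate_training_course

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def canonical_protocol():
    return build_protocol("up")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced four-arm closed-loop cohort shared by read-only tests."""
    return simulate_training_course(
        n_per_group={"experimental": 4, "age-control": 3,
                     "inverse-control": 3, "young-down": 3},
        seed=11, assign_stims=False)
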