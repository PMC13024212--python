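import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cysredox as cx

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Repository default parameter set (redox-balanced by construction)."""
    return cx.default_parameters()


@pytest.fixture(scope="session")
def y0():
    return cx.State(C=0.05, G=1.0, R=0.01, S=0.05, A=1.0)


@pytest.fixture(scope="session")
def nominal_traj(params, y0):
    """Accurate adaptive-solver trajectory over 24 h at repo defaults."""
    return cx.integrate(y0, params, 24.0)


def random_states(n, seed, scale=2.0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, scale, size=(n, 5))
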