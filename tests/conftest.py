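import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import synbm

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def solid():
    """Published 'Solid' parameter row (anti-Hebbian reproduction preset)."""
    return synbm.preset("table1_solid")


@pytest.fixture(scope="session")
def dotted():
    """Published 'Dotted' parameter row."""
    return synbm.preset("table1_dotted")


@pytest.fixture(scope="session")
def static5():
    return synbm.PresynapticSignal.static(5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240984)


def random_params(rng, sign=None):
    """A random admissible parameter set for property tests."""
    return synbm.ModelParams(
        gamma_mu=float(rng.uniform(0.05, 5.0)),
        gamma_w=float(rng.uniform(0.05, 5.0)),
        m_mu=float(rng.uniform(0.1, 10.0)),
        m_w=float(rng.uniform(0.1, 10.0)),
        mu_d=float(rng.uniform(-10, 10)),
        w_d=float(rng.uniform(-10, 10)),
        hebbian_sign=int(rng.choice([-1, 1])) if sign is None else sign,
    )
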