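import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mayleonard as ml
from mayleonard import fpt

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def minimal12() -> ml.MinimalParams:
    """Minimal-model parameters at the exact-analysis scale Omega = 12."""
    return ml.MinimalParams(r=1.0, alpha=0.8, beta=1.3, omega=12)


@pytest.fixture(scope="session")
def gen12(minimal12):
    """Truncated generator (n_max = 2*Omega) with the coordinate planes absorbing."""
    net = ml.build_minimal_network(minimal12)
    return fpt.build_generator(net, 24, absorbing="any_zero")


@pytest.fixture(scope="session")
def tau12(gen12):
    """Exact mean first-extinction time field at Omega = 12."""
    return fpt.mean_absorption_time(gen12)


@pytest.fixture(scope="session")
def symmetric12() -> np.ndarray:
    return np.array([4, 4, 4], dtype=np.int64)
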