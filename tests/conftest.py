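import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def numerical_gradient(fn, positions, ids, h=1e-6):
    """Central-difference gradient of a scalar function of particle positions."""
    grads = {}
    for pid in ids:
        g = np.zeros(3)
        for ax in range(3):
            pp = {k: v.copy() for k, v in positions.items()}
            pp[pid][ax] += h
            ep = fn(pp)
            pp[pid][ax] -= 2 * h
            em = fn(pp)
            g[ax] = (ep - em) / (2 * h)
        grads[pid] = g
    return grads


@pytest.fixture
def numgrad():
    return numerical_gradient
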