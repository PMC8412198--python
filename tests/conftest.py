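import warnings

import numpy as np
import pytest

from patcomm.gp import ObservedPattern
from patcomm.kernels import KernelSpec


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    """Mixed-model convergence chatter is expected on small simulated data."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def grid100():
    return np.linspace(0.0, 1.0, 100)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_pattern(grid100):
    """A noisy sine with period 0.2 on the canonical grid."""
    r = np.random.default_rng(7)
    y = np.sin(2 * np.pi * grid100 / 0.2) + r.normal(0, 0.05, grid100.size)
    return ObservedPattern.standardized(grid100, y)


@pytest.fixture
def rbf_spec():
    return KernelSpec("RBF", {"theta2": 1.0, "theta3": 0.2, "noise_var": 0.1})
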