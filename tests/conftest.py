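import numpy as np
import pytest

from mixmrf import make_phantom, smooth_phantom
from mixmrf.forward_model import degrade


@pytest.fixture(scope="session")
def sim1():
    """Hard-edge phantom, its PSF system matrix and one Poisson observation."""
    truth = make_phantom("paper1", 1099.0, 0.0)
    y, A = degrade(truth, kernel_sd=1.0, seed=11)
    return truth, y, A


@pytest.fixture(scope="session")
def sim2():
    """Smoothed phantom (400/75 base, Gaussian kernel sd 1.5) and observation."""
    truth = smooth_phantom(make_phantom("paper2", 400.0, 75.0), 1.5)
    y, A = degrade(truth, kernel_sd=1.0, seed=11)
    return truth, y, A


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def toy2_model():
    """A 1x2 toy inverse problem for quadrature cross-checks."""
    A = np.array([[0.7, 0.3], [0.2, 0.8]])
    y = np.array([6, 4])
    return A, y
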