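import numpy as np
import pytest

from burstnet import distributions as D
from burstnet import netgen as NG


@pytest.fixture(scope="session")
def exp_dist():
    return D.exponential(1.0)


@pytest.fixture(scope="session")
def weibull_sd2():
    return D.from_moments("weibull", 1.0, 2.0)


@pytest.fixture(scope="session")
def gamma_sd2():
    return D.from_moments("gamma", 1.0, 2.0)


@pytest.fixture(scope="session")
def lognormal_deg_7_05():
    """Degree model of the percolation experiments: lognormal(7, 0.5)."""
    return NG.DegreeModel.lognormal(7.0, 0.5)


@pytest.fixture(scope="session")
def small_net():
    """A ~2000-node configuration-model network with lognormal(7, 2) degrees."""
    dm = NG.DegreeModel.lognormal(7.0, 2.0)
    return NG.wire(NG.sample_degrees(dm, 2000, seed=101), seed=102)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
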