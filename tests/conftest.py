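import numpy as np
import pytest

from fmmdsim import (
    MAGNETITE,
    Environment,
    SizeDistribution,
)
from fmmdsim.langevin import (
    DemodGrid,
    EXPERIMENTAL_PROTOCOL,
    MC_PROTOCOL,
)


@pytest.fixture(scope="session")
def material():
    return MAGNETITE


@pytest.fixture(scope="session")
def nanomag():
    """Fitted nanomag-D size law (median 7.81 nm, width 0.346)."""
    return SizeDistribution(d0=7.81e-9, sigma=0.346, Np=1.0)


@pytest.fixture(scope="session")
def env318():
    """Measurement-head environment (coil heating, ~318 K)."""
    return Environment(T=318.0)


@pytest.fixture(scope="session")
def env300():
    """Simulation bath at 300 K, water viscosity, 20 nm hydrodynamic size."""
    return Environment(T=300.0)


@pytest.fixture(scope="session")
def grid():
    return DemodGrid()


@pytest.fixture(scope="session")
def exp_protocol():
    return EXPERIMENTAL_PROTOCOL


@pytest.fixture(scope="session")
def mc_protocol():
    return MC_PROTOCOL


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210511)
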