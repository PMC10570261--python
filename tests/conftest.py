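import numpy as np
import pytest

from cardiact import (
    FdgKinetics,
    GdKinetics,
    InfusionProtocol,
    simulate_plasma_curve,
)


@pytest.fixture(scope="session")
def protocol():
    return InfusionProtocol()


@pytest.fixture(scope="session")
def fdg_plasma(protocol):
    """Noiseless FDG plasma input on a 0.1-min grid."""
    return simulate_plasma_curve(
        protocol, vd=150.0, kel=0.1, grid=0.1, rate=protocol.fdg_rate, label="plasma_fdg"
    )


@pytest.fixture(scope="session")
def gd_plasma(protocol):
    """Noiseless contrast-agent plasma input (mM) on a 0.1-min grid."""
    return simulate_plasma_curve(protocol, vd=250.0, kel=0.05, grid=0.1, label="plasma_gd")


@pytest.fixture(scope="session")
def reference_fdg_kinetics():
    """The irreversible-model parameter set used in recovery checks (Ki = 0.025)."""
    return FdgKinetics(k1=0.1, k2=0.15, k3=0.05, vb=0.05, suppression_factor=1.0)


@pytest.fixture(scope="session")
def reference_gd_kinetics():
    return GdKinetics(ktrans=0.25, ve=0.48, vp=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
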