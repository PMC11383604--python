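import numpy as np
import pytest
from hypothesis import settings

from mmwrheo import BurgersParams, ForceProtocol, WireGeometry

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def params():
    """Reference liquid-like material used throughout the examples."""
    return BurgersParams(J1=0.1, J2=0.05, tau=2.0, eta0=200.0)


@pytest.fixture
def solid_params():
    return BurgersParams(J1=0.1, J2=0.05, tau=2.0, eta0=np.inf)


@pytest.fixture
def geometry():
    return WireGeometry()  # r = 12.3 um, L = 5.3 mm, h = 57 um


@pytest.fixture
def protocol():
    """Default acquisition protocol: 10 s on / 20 s off, twice, dt 0.5 s."""
    return ForceProtocol(F0=110e-9)
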