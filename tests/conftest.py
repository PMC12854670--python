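import math

import numpy as np
import pytest

from ciliaflow.flow_models import StokesletSphereField, VelocityField


class UniformStream(VelocityField):
    """Pure uniform flow -U z_hat, no sphere (sanity fields for metrics)."""

    def __init__(self, U: float):
        self.U = U
        self.spec = None

    def velocity(self, r, theta):
        theta = np.asarray(theta, dtype=float)
        return -self.U * np.cos(theta), self.U * np.sin(theta)

    def psi(self, r, theta):
        r = np.asarray(r, dtype=float)
        theta = np.asarray(theta, dtype=float)
        return -0.5 * self.U * r**2 * np.sin(theta) ** 2


@pytest.fixture(scope="session")
def stokeslet_sessile_L2():
    """Point force at L = 2a, unit strength, sphere held fixed."""
    return StokesletSphereField(2.0, 1.0, "sessile")


@pytest.fixture(scope="session")
def stokeslet_motile_L2():
    """Force-free swimmer, L = 2a, force calibrated to U = 2/3."""
    return StokesletSphereField(2.0, None, "motile")


@pytest.fixture
def theta_grid():
    return np.linspace(0.0, math.pi, 181)
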