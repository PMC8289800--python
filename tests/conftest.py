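"""Shared fixtures: the worked strategy family and its environments."""

import numpy as np
import pytest

from phenoswitch import (
    EnvironmentParams,
    make_general,
    make_preliminary,
    make_responsive,
    make_sleepless,
    make_stochastic,
)

ALPHA = 1 / 20


@pytest.fixture(scope="session")
def env_rare():
    """Rarely changing environment (long healthy spells)."""
    return EnvironmentParams(0.2, 0.1)


@pytest.fixture(scope="session")
def env_iid():
    """Symmetric coin-flip environment."""
    return EnvironmentParams(0.5, 0.5)


@pytest.fixture(scope="session")
def env_fast():
    """Frequently changing environment."""
    return EnvironmentParams(0.8, 0.6)


@pytest.fixture(scope="session")
def responsive_pair():
    return make_responsive(4.0, 4 * ALPHA, 0.2, 0.2)


@pytest.fixture(scope="session")
def preliminary_pair():
    return make_preliminary(4.0, 4 * ALPHA, 0.2, 0.2)


@pytest.fixture(scope="session")
def stochastic_pair():
    """Zero-determinant stochastic switcher of the worked family."""
    return make_stochastic(2.0, 2.0, ALPHA, 0.4, 0.4, 0.2, 0.2)


@pytest.fixture(scope="session")
def sleepless_pair():
    return make_sleepless(4.0, 4 * ALPHA)


def delta_pair(alpha: float):
    """Positive-determinant stochastic switcher (active-leaning)."""
    def m(e):
        s = alpha ** (e - 1)
        return np.array([[13 * s / 4, 3 * s / 4], [0.4, 0.4]])
    return make_general(m(1), m(2), "delta")


def nabla_pair(alpha: float):
    """Negative-determinant stochastic switcher (dormant-leaning)."""
    def m(e):
        s = alpha ** (e - 1)
        return np.array([[3 * s / 4, 13 * s / 4], [0.4, 0.4]])
    return make_general(m(1), m(2), "nabla")


@pytest.fixture(scope="session")
def delta_005():
    return delta_pair(0.05)


@pytest.fixture(scope="session")
def nabla_005():
    return nabla_pair(0.05)
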