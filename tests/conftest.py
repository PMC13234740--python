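import numpy as np
import pytest

from flavodoe import (
    GroundTruth,
    box_behnken,
    default_bbd_space,
    default_pbd_space,
    first_order_truth,
    plackett_burman,
    quadratic_truth,
)

# coded coordinates / decoded units of the reference quadratic's box maximum
TRUE_OPT_CODED = np.array([0.2517238067, -0.1610588752, -0.0842074307])
TRUE_OPT_ACTUAL = np.array([21.2586190345, 48.3894112494, 69.1579256924])
TRUE_OPT_VALUE = 20.8818493371


@pytest.fixture(scope="session")
def bbd_space():
    return default_bbd_space()


@pytest.fixture(scope="session")
def pbd_space():
    return default_pbd_space()


@pytest.fixture
def bbd_design(bbd_space):
    return box_behnken(3, 5, factor_names=bbd_space.names)


@pytest.fixture
def pbd_design(pbd_space):
    return plackett_burman(5, factor_names=pbd_space.names)


@pytest.fixture(scope="session")
def quad_truth():
    return quadratic_truth()


@pytest.fixture(scope="session")
def screening_truth():
    return first_order_truth()


@pytest.fixture
def noiseless():
    return GroundTruth(sigma=0.0)
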