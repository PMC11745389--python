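import numpy as np
import pytest

from epiland.landscape import EpistasisCoefficients, FitnessLandscape


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_l4(rng):
    """Random complete 4-site landscape."""
    return FitnessLandscape(4, rng.normal(size=16))


@pytest.fixture
def additive_l4():
    c = EpistasisCoefficients(4, {0: 1.0, 1: -0.5, 2: 0.25, 3: 2.0})
    return c.to_landscape()


@pytest.fixture(scope="session")
def fixture_landscape():
    from epiland.synthetic import make_antibody_like_landscape

    ls, coeffs = make_antibody_like_landscape()
    return ls, coeffs
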