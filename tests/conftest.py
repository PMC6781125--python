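import numpy as np
import pytest

import agedrift as ad


@pytest.fixture(scope="session")
def type2():
    return ad.build_type2(100)


@pytest.fixture(scope="session")
def modern():
    return ad.make_type1_modern()


@pytest.fixture(scope="session")
def preindustrial():
    return ad.make_type1_preindustrial()


@pytest.fixture(scope="session")
def headline_populations():
    """The three survivorship families with the standard Gaussian schedule."""
    return ad.default_populations()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_life_table(rng, k=None):
    """A small random but valid life table (strictly positive survivorship)."""
    k = k or rng.integers(4, 12)
    P = rng.uniform(0.4, 0.99, size=k - 1)
    l = np.concatenate(([1.0], np.cumprod(P)))
    return ad.LifeTable(l=l)
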