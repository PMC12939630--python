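import numpy as np
import pytest

from epifuse import generate_random, karate_club


@pytest.fixture
def path3():
    return generate_random("path", {"n": 3}, 0)


@pytest.fixture
def star4():
    return generate_random("star", {"n": 4}, 0)


@pytest.fixture(scope="session")
def karate():
    return karate_club()


def random_masses(rng: np.random.Generator, n: int) -> np.ndarray:
    """n random BPA triples, uniform on the probability simplex."""
    return rng.dirichlet(np.ones(3), size=n)
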