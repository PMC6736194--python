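import numpy as np
import pytest

from scads import StructureTemplate, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def d1d2c():
    return StructureTemplate.from_string("D1 D2 C", K=2)


@pytest.fixture
def small_dataset(d1d2c):
    """Low-dimensional two-block dataset with known sparse truth."""
    return generate(60, (10, 10), d1d2c, (0.2, 0.2, 0.6), 0.05, seed=7)


def standardized(X):
    return (X - X.mean(0)) / X.std(0, ddof=1)
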