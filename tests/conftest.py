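import numpy as np
import pytest

TINY_GRID = (12, 48, 128)  # (slow, fast, depth) for fast geometry checks
SMALL_GRID = (24, 96, 256)


@pytest.fixture(scope="session")
def tiny_grid():
    return TINY_GRID


@pytest.fixture(scope="session")
def small_grid():
    return SMALL_GRID


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
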