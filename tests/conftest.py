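import numpy as np
import pytest

from lcecg import build_fref, design_bank, gen_dataset


@pytest.fixture(scope="session")
def fref_grid():
    return build_fref(75.0, 360.0, 16)


@pytest.fixture(scope="session")
def filter_bank(fref_grid):
    return design_bank(fref_grid)


@pytest.fixture(scope="session")
def small_beatset():
    """Five beats per class on a reduced dense grid (fast, still >2x band)."""
    return gen_dataset(5, noise_sd=0.03, seed=11, fs_dense=14_400.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
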