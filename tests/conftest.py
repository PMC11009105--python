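import numpy as np
import pytest

from gridshift.grid import make_grid
from gridshift.synthetic import generate_dataset


@pytest.fixture(scope="session")
def grid5():
    return make_grid(5, 5)


@pytest.fixture(scope="session")
def small_dataset():
    """One shared desk-top dataset: 8x8 grid, 40 species, 3 periods."""
    return generate_dataset(seed=42, n_rows=8, n_cols=8, n_species=40)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
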