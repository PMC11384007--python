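import numpy as np
import pytest

from snow.toy_sim import ToyDesign, simulate_toy


@pytest.fixture(scope="session")
def small_toy():
    """A small rhythmic/flat dataset shared by fast tests."""
    design = ToyDesign(n_cells=200, n_types=3, n_rhythmic=20, n_flat=10)
    return simulate_toy(design, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
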