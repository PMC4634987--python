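import numpy as np
import pytest

from oralcna import simulate


@pytest.fixture(scope="session")
def toy_genome_grid():
    """Two chromosomes, two bands per arm, dense probes."""
    return simulate.generate_genome(
        n_chromosomes=2, arm_bands=2, band_len=1_000_000, probe_spacing=50_000, seed=3
    )


@pytest.fixture(scope="session")
def toy_genome(toy_genome_grid):
    return toy_genome_grid[0]


@pytest.fixture(scope="session")
def toy_grid(toy_genome_grid):
    return toy_genome_grid[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
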