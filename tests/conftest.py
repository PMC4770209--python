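import numpy as np
import pytest

from foxcobind.io_formats import Genome
from foxcobind.synthetic_data import simulate_genome


@pytest.fixture(scope="session")
def uniform_genome_100kb() -> Genome:
    return simulate_genome(n_chroms=1, chrom_len=100_000, seed=11)


@pytest.fixture(scope="session")
def uniform_genome_3x() -> Genome:
    """Three 50-kb chromosomes, uniform base composition."""
    return simulate_genome(n_chroms=3, chrom_len=50_000, seed=23)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
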