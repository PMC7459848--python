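import numpy as np
import pytest

from readrescue import SimConfig, simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def small_genome():
    """A 5 kb single-chromosome random genome shared across tests."""
    return simulate_genome(5_000, seed=7)


@pytest.fixture(scope="session")
def small_reads(small_genome):
    """Error-free 100 bp reads drawn from the small genome."""
    config = SimConfig(
        genome_len=5_000, n_reads=60, read_len=100,
        snp_rate=0.0, error_rate=0.0, seed=3,
    )
    return simulate_reads(small_genome, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
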