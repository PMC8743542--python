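import numpy as np
import pytest

from linarch.parsscan import genome_background, load_default_matrix
from linarch.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_cfg():
    """A compact synthetic replicon that still exercises every feature."""
    return SyntheticConfig(
        length=400_000,
        tir_perfect=1_500,
        tir_imperfect_extra=800,
        island_size=25_000,
        island_fraction=0.5,
        n_pars=20,
        replicon_id="mini",
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return generate(small_cfg, seed=101)


@pytest.fixture(scope="session")
def default_matrix(small_genome):
    rec, _ = small_genome
    return load_default_matrix(genome_background(rec))


@pytest.fixture()
def rng():
    return np.random.default_rng(20210692)
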