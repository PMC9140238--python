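import numpy as np
import pytest

from histolife import SimulationConfig, make_genome, make_strain_map


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11, n_strains=20, read_depth=20_000, n_chromosomes=4, n_genes=80
    )


@pytest.fixture(scope="session")
def small_layout(small_config):
    return make_genome(small_config)


@pytest.fixture(scope="session")
def small_map(small_config):
    return make_strain_map(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
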