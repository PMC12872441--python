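import warnings

import numpy as np
import pytest

from codonscape.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down experiment: 60 host + 20 viral genes, two replicates,
    four infection timepoints — small enough for the whole suite."""
    return SimulationConfig(
        seed=11,
        n_host_genes=60,
        n_virus_genes=20,
        total_footprints=400000,
        rna_depth=200000,
        n_trna_reads=4000,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
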