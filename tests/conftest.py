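import numpy as np
import pytest

from coolsuite import synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_config():
    return synthdata.SimulationConfig(
        chrom_length=60_000,
        n_genes=6,
        seed=11,
        cells_per_stage={"ES": 4},
        n_reads_per_cell=300,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return synthdata.simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_cells(small_truth, small_config):
    return synthdata.simulate_cells(small_truth, small_config)


@pytest.fixture(scope="session")
def deep_config():
    # full site recovery and deep pooled coverage: calibration regime
    return synthdata.SimulationConfig(
        chrom_length=60_000,
        n_genes=6,
        seed=7,
        cells_per_stage={"ES": 6},
        site_detection_prob=1.0,
        fixed_depth=6,
        n_reads_per_cell=0,
        linker_accessible=False,
    )


@pytest.fixture(scope="session")
def deep_truth(deep_config):
    return synthdata.simulate_genome(deep_config)


@pytest.fixture(scope="session")
def deep_cells(deep_truth, deep_config):
    return synthdata.simulate_cells(deep_truth, deep_config)
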