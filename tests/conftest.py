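import pytest

from irdm.simulate import SimulationConfig, simulate_dataset
from irdm import pipeline


@pytest.fixture(scope="session")
def default_dataset():
    """One full simulation at the study-condition defaults."""
    return simulate_dataset(SimulationConfig(), seed=7)


@pytest.fixture(scope="session")
def default_call_set(default_dataset):
    """Two-replica IRDM calling on every cell line of the default run."""
    return pipeline.analyze_dataset(default_dataset, seed=11)


@pytest.fixture()
def small_config():
    return SimulationConfig(
        n_cgis=60, chromosome_layout={"chr1": 40, "chrX": 20},
        n_cell_lines=2, n_genes=15)
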