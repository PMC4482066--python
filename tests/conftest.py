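import numpy as np
import pytest

from p53scape.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_bundle():
    """One default-scale synthetic cohort shared across tests."""
    return simulate_all(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_config():
    """A reduced configuration for tests that re-simulate repeatedly."""
    return SimulationConfig(
        seed=11,
        chrom_lengths={"chr1": 1_000_000, "chr2": 1_000_000},
        n_genes=80,
        n_lincrnas=20,
        n_peaks=60,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20150416)
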