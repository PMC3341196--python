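import numpy as np
import pytest

from tagnorm.count_data import CountMatrix
from tagnorm.simulator import SimulationParams, simulate_counts


@pytest.fixture
def tiny_cm():
    """2 genes x 2 samples with known column sums."""
    return CountMatrix(["g1", "g2"], np.array([[1, 2], [3, 4]]), ["A", "B"])


@pytest.fixture
def small_cm():
    """Random 50-gene, 6-sample matrix with moderate counts."""
    rng = np.random.default_rng(7)
    counts = rng.poisson(50, size=(50, 6)) + 1
    return CountMatrix([f"g{i}" for i in range(50)], counts,
                       ["A", "A", "A", "B", "B", "B"])


@pytest.fixture(scope="session")
def sim_biased():
    """Simulation with biased DE (P_DEG=20%, P_A=90%) at reduced scale."""
    params = SimulationParams(n_genes=2000, pdeg=0.20, pa=0.90, seed=11)
    return simulate_counts(params)


@pytest.fixture(scope="session")
def sim_unbiased():
    """Simulation with symmetric DE (P_A=50%) at reduced scale."""
    params = SimulationParams(n_genes=2000, pdeg=0.20, pa=0.50, seed=12)
    return simulate_counts(params)
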