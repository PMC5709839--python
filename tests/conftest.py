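import numpy as np
import pytest

from autozyg.data_io import GeneticMap, GenotypePanel
from autozyg.simulator import SimulationConfig, run_forward


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_panel(rng):
    """25 random sites x 8 individuals with phased haplotypes."""
    S, N = 25, 8
    pos = np.sort(rng.choice(10_000_000, S, replace=False)).astype(np.int64) + 1
    hap = rng.integers(0, 2, size=(S, 2 * N)).astype(np.int8)
    geno = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)
    panel = GenotypePanel([f"i{j}" for j in range(N)], {"1": pos}, {"1": geno},
                          haplotypes={"1": hap})
    panel.validate()
    return panel


@pytest.fixture
def toy_map():
    return GeneticMap({"1": (np.array([1, 10_000_000], dtype=np.int64),
                             np.array([0.0, 0.1]))})


@pytest.fixture(scope="session")
def tiny_sim():
    """Small, fast forward simulation (error-free) for structural checks."""
    cfg = SimulationConfig(scenario=1, g_max_morgans=0.065,
                           n_predetermined=14_500, n_e=30, n_generations=40,
                           sample_n=20, seed=42)
    return run_forward(cfg)
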