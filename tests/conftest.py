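import numpy as np
import pandas as pd
import pytest

from endopheno.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale, well-separated planted simulation: strong SNP effect."""
    return SimulationConfig(
        n_subtypes=3,
        samples_per_subtype=24,
        informative_genes_per_subtype=40,
        pi_noninformative=0.7,
        delta_maf=0.9,
        beta=1.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def paper_scale_dataset():
    """One replicate at the reference study scale (3 x 80 samples, 1600 genes)."""
    config = SimulationConfig(delta_maf=0.8, beta=0.8, seed=7)
    return simulate_dataset(config)


@pytest.fixture()
def planted_block_matrix():
    """Exactly separable non-negative matrix with 3 planted sample blocks."""
    rng = np.random.default_rng(0)
    m, per = 30, 8
    V = np.full((m, 3 * per), 0.05)
    for b in range(3):
        rows = slice(b * 10, (b + 1) * 10)
        cols = slice(b * per, (b + 1) * per)
        V[rows, cols] = 5.0 + rng.random((10, per))
    labels = np.repeat([1, 2, 3], per)
    return V, labels
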