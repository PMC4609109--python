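import numpy as np
import pandas as pd
import pytest

from thermoadapt import (
    SimulationConfig,
    average_replicates,
    global_normalize,
    simulate,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One paper-design synthetic dataset (32 arrays, 4000 genes), seed 0."""
    return simulate(seed=0)


@pytest.fixture(scope="session")
def default_profiles(default_dataset):
    ds = default_dataset
    return average_replicates(global_normalize(ds.matrix), ds.meta)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Deterministic dataset: no replicate noise, no epistasis."""
    cfg = SimulationConfig(n_genes=500, noise_sd=0.0, epistasis_coef=0.0)
    return simulate(config=cfg, seed=3, n_sets=0)


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(1, 101)]
    samples = [f"s{j}" for j in range(1, 6)]
    return pd.DataFrame(rng.normal(size=(100, 5)), index=genes, columns=samples)
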