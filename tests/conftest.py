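import numpy as np
import pytest

import screscue as sr


@pytest.fixture(scope="session")
def small_cfg() -> sr.SimConfig:
    """A scaled-down simulation for fast unit tests."""
    return sr.SimConfig(n_clusters=2, cells_per_group_per_cluster=60, n_genes=500)


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return sr.simulate_counts(small_cfg, seed=11)


@pytest.fixture(scope="session")
def small_norm(small_data):
    adata, _ = small_data
    # min_genes=0: the scaled-down gene universe cannot reach the default 600
    return sr.normalize_cp10k(sr.apply_qc(adata, min_genes=0))


@pytest.fixture(scope="session")
def small_truth(small_data):
    return small_data[1]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
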