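import logging

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

# the iteration-cap warning is expected at tight epsilon; keep test logs quiet
logging.getLogger("rdaclone.rda").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_clone_block():
    """Clean rank-1-per-block two-clone matrix: 20 cells x 10 sites."""
    row_a = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=float)
    row_b = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
    X = np.vstack([np.tile(row_a, (10, 1)), np.tile(row_b, (10, 1))])
    labels = np.array([0] * 10 + [1] * 10)
    return X, labels


@pytest.fixture
def small_dataset():
    """Modest simulated dataset with default noise for clustering tests."""
    from rdaclone import SimulationConfig, simulate_dataset

    return simulate_dataset(
        SimulationConfig(n_cells=150, n_sites=100, n_subclones=5, seed=11)
    )
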