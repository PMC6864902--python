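import numpy as np
import pytest

import seedpls as sp


@pytest.fixture(scope="session")
def truth_small():
    """Default planted ground truth (12^3 grid, 120 active voxels)."""
    return sp.make_ground_truth(seed=11)


@pytest.fixture(scope="session")
def planted_dataset(truth_small):
    """Small planted study: 12 subjects, 6 trials per condition."""
    return sp.simulate_dataset(truth_small, n_subjects=12,
                               n_trials_per_condition=6, seed=5)


@pytest.fixture(scope="session")
def prepared(planted_dataset):
    """(datamat, variable block, info) after the full preparation chain."""
    return sp.prepare_from_dataset(planted_dataset)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Deterministic regime: coupling 1, noise_sd 0 (rank-one downstream)."""
    truth = sp.make_ground_truth(seed=3, coupling_strength=1.0, noise_sd=0.0)
    return sp.simulate_dataset(truth, n_subjects=10,
                               n_trials_per_condition=2, seed=4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
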