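"""Shared fixtures: synthetic datasets and one pooled CV run reused across tests."""

import numpy as np
import pytest

from hazardcp import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """400 compounds, noise-free labels (a pure function of structure)."""
    config = SyntheticConfig(n_compounds=400, label_noise=0.0, seed=11)
    records, truth = generate_dataset(config)
    return records, truth


@pytest.fixture(scope="session")
def smiles_battery(small_dataset):
    """Standardized SMILES strings covering rings, branches, stereo, salts."""
    records, _ = small_dataset
    return [r.smiles_std for r in records]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(11)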