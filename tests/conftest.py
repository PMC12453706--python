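import numpy as np
import pytest

from hgmda import ExperimentConfig, build_balanced_pairs, generate_synthetic_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted():
    """A small planted-block dataset with strong recoverable signal."""
    return generate_synthetic_dataset(
        n_microbes=60, n_diseases=24, n_blocks=3, p_in=0.7, p_out=0.03, seed=42
    )


@pytest.fixture(scope="session")
def tiny_config():
    """A fast training configuration for unit tests."""
    return ExperimentConfig(
        epochs=40, lr=0.002, weight_decay=0.00005, dropout=0.0,
        k_neigs=5, clusters=3, n_head=2, nlayer=1,
        d_hidden=24, d_view=8, d_embed=16, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_trained(planted, tiny_config):
    """One trained model on the planted data, shared across tests."""
    from hgmda import train_model

    pairs = build_balanced_pairs(planted.dataset, 1.0, seed=3)
    return train_model(planted.dataset, tiny_config, pairs), pairs
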