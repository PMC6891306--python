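import numpy as np
import pytest

from circrbp.cnn_model import ModelConfig, build_model, train
from circrbp.sequence_io import split_dataset
from circrbp.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_planted():
    """Small planted-motif dataset with ground truth (300 pairs, seed 11)."""
    cfg = SyntheticConfig(n_pairs=300, seed=11)
    records, truth = generate_dataset(cfg)
    return records, truth, cfg


@pytest.fixture(scope="session")
def small_split(small_planted):
    records, _, _ = small_planted
    return split_dataset(records, seed=11)


@pytest.fixture(scope="session")
def tiny_trained_model(small_split):
    """A quickly trained reduced-scale model for motif/prediction tests."""
    cfg = ModelConfig(
        kernel_sizes=[8, 20, 38],
        kernels_per_size=8,
        batch_size=64,
        max_epochs=8,
        patience=4,
        seed=11,
    )
    model = build_model(cfg, L=100)
    return train(model, small_split, cfg)
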