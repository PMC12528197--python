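"""Shared fixtures: synthetic task data and a trained small model.

The expensive pieces (the 400-epoch two-class task and one training run
on it) are session-scoped so every test that needs a trained model reuses
the same seeded run.
"""

import numpy as np
import pytest

from eegformer import (
    ModelConfig,
    TrainSpec,
    make_classification_task,
    train,
)

TASK_SEED = 11


def small_config(**overrides) -> ModelConfig:
    base = dict(
        n_layers=2, n_heads=4, d_model=64, d_ff=128, n_classes=2,
        n_channels=8, seq_len=16, frame_dim=32, layout="raw_frames", seed=0,
    )
    base.update(overrides)
    return ModelConfig(**base)


def tiny_config(**overrides) -> ModelConfig:
    base = dict(
        n_layers=2, n_heads=2, d_model=8, d_ff=16, n_classes=2,
        n_channels=2, seq_len=4, frame_dim=6, seed=3,
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def task_data():
    """Two-class (alpha- vs theta-dominant) task: 400 epochs, 8 channels."""
    return make_classification_task(n_epochs_per_class=200, n_channels=8, seed=TASK_SEED)


@pytest.fixture(scope="session")
def trained(task_data):
    """One seeded training run of the small configuration on the task."""
    spec = TrainSpec(lr=0.001, batch_size=32, max_epochs=15, patience=5, seed=0)
    return train(task_data, small_config(), spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
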