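"""Shared fixtures: desk-scale datasets and configs, generated at test time."""

import numpy as np
import pytest

from mmlmh import (
    MultimodalHealthModel,
    SyntheticDatasetSpec,
    TrainConfig,
    generate,
)
from mmlmh.pipeline import stratified_split


@pytest.fixture(scope="session")
def default_dataset():
    """The standard 600-sample, 3-class fixture."""
    return generate(SyntheticDatasetSpec(seed=11))


@pytest.fixture(scope="session")
def regression_dataset():
    return generate(SyntheticDatasetSpec(task="regression", n_samples=300, seed=12))


@pytest.fixture(scope="session")
def small_config():
    return TrainConfig.small(task="classification", seed=0)


@pytest.fixture(scope="session")
def tiny_fit(default_dataset, small_config):
    """A short seeded training run shared by tests that need a fitted model."""
    train, val, test = stratified_split(default_dataset, seed=0)
    model = MultimodalHealthModel(train, small_config, validation=val)
    results = model.fit(epochs=3)
    return results, train, val, test


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
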