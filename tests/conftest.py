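"""Shared fixtures: small synthetic cohorts and fast training configs.

Everything is generated at test time; fixture sizes are kept small (16x16
images, tens of samples) wherever the property under test does not depend
on scale.
"""

import numpy as np
import pytest

from coldstart_al import (
    MCDropoutConfig,
    SyntheticDatasetSpec,
    TrainingConfig,
    encode,
    generate_dataset,
    make_encoder,
    stratified_split,
)


@pytest.fixture(scope="session")
def tiny_spec():
    return SyntheticDatasetSpec(
        n_samples=60,
        n_positive=45,
        image_width=16,
        image_height=16,
        latent_dim=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return generate_dataset(tiny_spec)


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset):
    return stratified_split(tiny_dataset, 0.5, seed=3)


@pytest.fixture(scope="session")
def oracle_encoder():
    return make_encoder("oracle_informative", embedding_dim=8, informativeness=0.9, seed=2)


@pytest.fixture(scope="session")
def tiny_embeddings(oracle_encoder, tiny_dataset):
    return encode(oracle_encoder, tiny_dataset)


@pytest.fixture(scope="session")
def fast_train():
    """Classifier config cut to sizes where optimization quality is irrelevant."""
    return TrainingConfig(max_epochs=15, early_stop_patience=15, seed=7)


@pytest.fixture(scope="session")
def fast_estimator():
    return TrainingConfig(
        learning_rate=1e-4, loss="mean_squared_error", max_epochs=10, early_stop_patience=10, seed=7
    )


@pytest.fixture(scope="session")
def fast_mc():
    return MCDropoutConfig(n_passes=10, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
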