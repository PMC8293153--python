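"""Shared fixtures: phantoms, the augmented training set and a fitted scorer.

The expensive session fixtures mirror the training conditions used
throughout the package: 73 synthetic maps, 20 augmented samples each,
and a grid-searched random-forest fitness model.
"""

import numpy as np
import pytest

from evoseg.classifier import augment_samples, train_fitness_model
from evoseg.phantom import PhantomSpec, generate_dataset, generate_phantom

DATASET_SEED = 11
AUGMENT_SEED = 1


@pytest.fixture(scope="session")
def phantom_dataset():
    """73 synthetic annotated maps, the training corpus size."""
    return generate_dataset(73, seed=DATASET_SEED)


@pytest.fixture(scope="session")
def training_samples(phantom_dataset):
    rng = np.random.default_rng(AUGMENT_SEED)
    samples = []
    for i, pair in enumerate(phantom_dataset):
        samples.extend(augment_samples(pair, rng=rng, source=f"phantom-{i}"))
    return samples


@pytest.fixture(scope="session")
def fitness_model(training_samples):
    return train_fitness_model(training_samples, family="rf", seed=1)


@pytest.fixture()
def small_pair():
    """A cheap 2-subunit phantom for unit tests."""
    return generate_phantom(PhantomSpec(n_subunits=2, grid_shape=(28, 28, 28),
                                        blob_radius=(3.0, 4.5), seed=5))


@pytest.fixture()
def five_subunit_pair():
    return generate_phantom(PhantomSpec(n_subunits=5, grid_shape=(40, 40, 40),
                                        seed=1000))
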