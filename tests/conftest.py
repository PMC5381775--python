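"""Shared fixtures: seeded training sets and trained models.

Session scope: SVM fits are the expensive step and the fixtures are
read-only for every test that uses them.
"""

from __future__ import annotations

import numpy as np
import pytest

import stainmap as sm
from stainmap.classes import StainClass

#: The simulator's default class color means, used throughout the tests.
GAUSSIAN_MEANS = {
    StainClass.ADIPOGENIC: (180, 60, 60),
    StainClass.OSTEOGENIC: (60, 60, 180),
    StainClass.NEGATIVE: (200, 200, 200),
}


def gaussian_training_features(seed: int = 42, n_per_class: int = 1000, sd: float = 10.0):
    """Isotropic Gaussian RGB clusters, one per class, in a fixed order."""
    rng = np.random.default_rng(seed)
    feats, labs = [], []
    for cls in StainClass:
        x = rng.normal(GAUSSIAN_MEANS[cls], sd, size=(n_per_class, 3))
        feats.append(np.clip(np.rint(x), 0, 255).astype(np.int64))
        labs.append(np.full(n_per_class, int(cls), dtype=np.int64))
    return np.concatenate(feats), np.concatenate(labs)


@pytest.fixture(scope="session")
def gaussian_training_set() -> sm.TrainingSet:
    feats, labs = gaussian_training_features()
    return sm.TrainingSet(feats, labs, provenance=["gaussian-seed42"])


@pytest.fixture(scope="session")
def gaussian_model(gaussian_training_set) -> sm.ClassifierModel:
    return sm.train(gaussian_training_set)


@pytest.fixture(scope="session")
def constant_training_set() -> sm.TrainingSet:
    """Perfectly separable constant-color classes, 100 samples each."""
    colors = {
        StainClass.ADIPOGENIC: (255, 0, 0),
        StainClass.OSTEOGENIC: (0, 0, 255),
        StainClass.NEGATIVE: (255, 255, 255),
    }
    feats = np.concatenate([np.tile(colors[c], (100, 1)) for c in StainClass])
    labs = np.concatenate([np.full(100, int(c)) for c in StainClass])
    return sm.TrainingSet(feats, labs)


@pytest.fixture(scope="session")
def constant_model(constant_training_set) -> sm.ClassifierModel:
    return sm.train(constant_training_set)


@pytest.fixture(scope="session")
def mean_color_model() -> sm.ClassifierModel:
    """Model trained on the simulator's exact default class means."""
    crops = sm.simulate_training_crops(crop_size=10, noise_sd=0.0, seed=0)
    return sm.train(sm.training_set_from_crops(crops))
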