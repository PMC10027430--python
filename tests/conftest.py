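"""Shared fixtures: toy structures, small models, and trained classifiers.

The two trained classifiers are expensive (minutes on one CPU) and
session-scoped; every test that needs a trained model shares them.
"""

from __future__ import annotations

import numpy as np
import pytest

from envdesign import dataset, model

# Conditions for the parameter-recovery experiment: the reference rule at
# label-noise 0.2 (Bayes accuracy 0.81), 5000 training environments.
RECOVERY_NOISE = 0.2
RECOVERY_N_TRAIN = 5000
RECOVERY_N_TEST = 2000
RECOVERY_TRAIN_SEED = 11
RECOVERY_TEST_SEED = 99

# Reduced-width architecture used for trained-model tests (the package
# default stays at 16 heads × 16 dims).
SMALL_CONFIG = model.ModelConfig(layers=3, heads=4, head_dim=8, seed=0)


@pytest.fixture(scope="session")
def helix30():
    return dataset.make_ideal_backbone(30, "helix", seed=777, name="helix30")


@pytest.fixture(scope="session")
def helix10():
    return dataset.make_ideal_backbone(10, "helix", seed=3, name="helix10")


@pytest.fixture(scope="session")
def recovery_data():
    """Train/held-out toy-rule datasets at the study's noise level."""
    train = dataset.make_toy_rule_dataset(
        RECOVERY_N_TRAIN,
        dataset.ToyRuleParams(noise=RECOVERY_NOISE, seed=RECOVERY_TRAIN_SEED),
    )
    test = dataset.make_toy_rule_dataset(
        RECOVERY_N_TEST,
        dataset.ToyRuleParams(noise=RECOVERY_NOISE, seed=RECOVERY_TEST_SEED),
    )
    return train, test


@pytest.fixture(scope="session")
def recovery_model(recovery_data):
    """Classifier trained on the noisy reference-rule generator."""
    train, _ = recovery_data
    clf = model.init_model(SMALL_CONFIG)
    clf, trace = model.train(
        clf,
        [s.features.matrix for s in train],
        [s.label for s in train],
        model.TrainingConfig(epochs=200, seed=0),
    )
    return clf, trace


@pytest.fixture(scope="session")
def geometric_model():
    """Classifier trained to reproduce the geometry-only rule on toy backbones.

    Trained at zero label noise, so its argmax should equal the rule
    labeling for every environment of a toy backbone — the setting where
    iterative design has an exact known fixed point.
    """
    samples = dataset.make_backbone_rule_dataset(
        60, dataset.ToyRuleParams(noise=0.0, rule="geometric", seed=5)
    )
    clf = model.init_model(SMALL_CONFIG)
    clf, _ = model.train(
        clf,
        [s.features.matrix for s in samples],
        [s.label for s in samples],
        model.TrainingConfig(epochs=250, seed=0),
    )
    return clf


@pytest.fixture()
def uniform_model():
    """A classifier that outputs the uniform distribution for any input.

    Zeroing the head of a freshly initialized model makes all logits
    equal, which gives closed-form expectations for pseudo-likelihoods
    and makes argmax deterministically pick type index 0 (ALA).
    """
    clf = model.init_model(model.ModelConfig(layers=1, heads=2, head_dim=8, seed=0))
    clf.params["head.W"][:] = 0.0
    clf.params["head.b"][:] = 0.0
    return clf
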