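"""Shared fixtures.

The expensive session fixtures (the simulated study cohort and the models
trained on it) are built once and shared across test modules so the whole
suite stays within a desk-scale runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

import dfenet as df

#: Study-scale cohort settings: 100 subjects, split 60/20/20 by subject.
COHORT_SEED = 7
#: Training length for the session models (within the 30-epoch budget the
#: recovery check allows; the default network plateaus around epoch 11-15).
TRAIN_EPOCHS = 15


@pytest.fixture(scope="session")
def cohort():
    """100-subject synthetic cohort with default simulation parameters."""
    return df.simulate_cohort(df.SimParams(seed=COHORT_SEED), 100)


@pytest.fixture(scope="session")
def cohort_split(cohort):
    """Subject-wise 60/20/20 train/validation/test split."""
    train, val, test = df.holdout_split(cohort, (0.6, 0.2, 0.2))
    return train, val, test


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-subject cohort for cheap structural tests."""
    return df.simulate_cohort(df.SimParams(seed=11), 6)


def _train(cohort, subjects, variant, seed):
    model, history = df.train_on_dataset(
        cohort, subjects,
        net_config=df.NetworkConfig(se_variant=variant),
        train_config=df.TrainConfig(epochs=TRAIN_EPOCHS, seed=seed),
    )
    model._loss_history = history
    return model


@pytest.fixture(scope="session")
def trained_model(cohort, cohort_split):
    """Default network (cSE, P5) trained on the 60 training subjects."""
    return _train(cohort, cohort_split[0], "cSE", 0)


@pytest.fixture(scope="session")
def sfra_model(cohort, cohort_split):
    """Plain dense network (no SE) trained identically to ``trained_model``."""
    return _train(cohort, cohort_split[0], "none", 0)


@pytest.fixture(scope="session")
def trained_models_pair(trained_model, sfra_model):
    """(SE-enhanced, plain) models for feature-map comparisons."""
    return trained_model, sfra_model


@pytest.fixture(scope="session")
def ablation_rmses(cohort, cohort_split, trained_model, sfra_model):
    """(variant, seed) -> pooled test RMSE over 3 seeds for both variants.

    Seed 0 reuses the session's two trained models.
    """
    train_subjects, _, test_subjects = cohort_split
    test_ds = cohort.for_subjects(test_subjects)
    results = {
        ("cSE", 0): df.evaluate(trained_model, test_ds).rmse,
        ("none", 0): df.evaluate(sfra_model, test_ds).rmse,
    }
    for seed in (1, 2):
        for variant in ("cSE", "none"):
            model = _train(cohort, train_subjects, variant, seed)
            results[(variant, seed)] = df.evaluate(model, test_ds).rmse
    return results


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
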