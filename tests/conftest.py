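"""Shared fixtures: the packaged taxonomy and small simulated datasets.

All synthetic data are generated at test time from fixed seeds; nothing is
loaded from disk except the packaged taxonomy and compendium tables.
"""

import numpy as np
import pandas as pd
import pytest

from comblearn import classify, features, simulate
from comblearn.taxonomy import default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def small_training(taxonomy):
    """20 instances per profile per regime; shared across model tests."""
    return simulate.build_training_set(
        taxonomy, instances_per_profile=20, rng_seed=101)


@pytest.fixture(scope="session")
def small_test_set(taxonomy):
    return simulate.build_training_set(
        taxonomy, instances_per_profile=8, rng_seed=102)


def featurize_training(ts, regimes=None):
    """Per-regime moderated feature tables -> dict regime: (X, y)."""
    out = {}
    for ratio in regimes or sorted(ts.table["regime"].unique()):
        sub = ts.table[ts.table["regime"] == ratio]
        reps = sub[ts.replicate_columns()].to_numpy().reshape(
            len(sub), 4, ts.n_reps)
        table, _ = features.featurize(reps)
        out[ratio] = (table, sub["profile_id"].to_numpy())
    return out


def stack_features(per_regime):
    X = pd.concat([per_regime[r][0] for r in per_regime], ignore_index=True)
    y = np.concatenate([per_regime[r][1] for r in per_regime])
    return X, y


@pytest.fixture(scope="session")
def training_features(small_training):
    return featurize_training(small_training)


@pytest.fixture(scope="session")
def test_features_by_regime(small_test_set):
    return featurize_training(small_test_set)


@pytest.fixture(scope="session")
def rf_model(taxonomy, training_features):
    """Random Forest on the small training set (reduced tree count keeps
    the unit suite fast; the acceptance tests train at full defaults)."""
    X, y = stack_features(training_features)
    return classify.train_classifier(
        X, y, "random_forest", {"n_estimators": 100}, seed=7,
        taxonomy=taxonomy)
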