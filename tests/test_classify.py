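"""Classifier contracts: probability simplex, determinism, baselines."""

import numpy as np
import pandas as pd
import pytest

from comblearn import classify as cl

from conftest import stack_features


def test_predict_proba_is_a_probability_simplex(rf_model,
                                                test_features_by_regime):
    X, _ = test_features_by_regime[4.0]
    probs = rf_model.predict_proba(X.iloc[:50])
    assert probs.shape == (50, 123)
    assert np.all(probs >= 0)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


def test_rf_memorizes_its_training_set(taxonomy, training_features):
    X, y = stack_features(training_features)
    model = cl.train_classifier(
        X.iloc[:2000], y[:2000], "random_forest",
        {"n_estimators": 60, "min_samples_leaf": 1}, seed=3)
    pred, _ = model.predict(X.iloc[:2000])
    assert (pred == y[:2000]).mean() == 1.0


def test_training_is_seed_deterministic(training_features,
                                        test_features_by_regime, taxonomy):
    X, y = stack_features(training_features)
    Xt, _ = test_features_by_regime[2.0]
    a = cl.train_classifier(X, y, "random_forest", {"n_estimators": 30},
                            seed=5, taxonomy=taxonomy)
    b = cl.train_classifier(X, y, "random_forest", {"n_estimators": 30},
                            seed=5, taxonomy=taxonomy)
    np.testing.assert_array_equal(a.predict_proba(Xt.iloc[:100]),
                                  b.predict_proba(Xt.iloc[:100]))


def test_unknown_and_missing_labels_are_rejected(taxonomy,
                                                 training_features):
    X, y = stack_features(training_features)
    bad = y.copy()
    bad[0] = 999
    with pytest.raises(cl.ClassifierError, match="999"):
        cl.train_classifier(X, bad, "random_forest", taxonomy=taxonomy)
    keep = y != 3
    with pytest.raises(cl.ClassifierError, match=r"\b3\b"):
        cl.train_classifier(X[keep], y[keep], "random_forest",
                            taxonomy=taxonomy)


def test_feature_schema_mismatch_is_rejected(rf_model):
    with pytest.raises(cl.ClassifierError, match="schema"):
        rf_model.predict_proba(np.zeros((2, 7)))
    renamed = pd.DataFrame(np.zeros((2, 19)),
                           columns=[f"x{i}" for i in range(19)])
    with pytest.raises(cl.ClassifierError, match="schema"):
        rf_model.predict_proba(renamed)


def test_deterministic_matcher_gives_one_hot_probabilities(taxonomy):
    model = cl.train_classifier(None, np.array(taxonomy.ids),
                                "deterministic", taxonomy=taxonomy)
    vecs = np.vstack([taxonomy.witness(pid) for pid in (1, 3, 60)])
    feats = np.zeros((3, 19))
    feats[:, :4] = vecs
    probs = model.predict_proba(feats)
    assert set(np.unique(probs)) == {0.0, 1.0}
    np.testing.assert_allclose(probs.sum(axis=1), 1.0)
    pred, p = model.predict(feats)
    assert list(pred) == [1, 3, 60]
    assert np.all(p == 1.0)


def test_log_gain_limits(taxonomy):
    """Perfect one-hot predictions give log gain 0; uniform probabilities
    give ln(123)."""

    class Uniform(cl.TrainedClassifier):
        def predict_proba(self, features):
            n = np.asarray(features).shape[0]
            return np.full((n, 123), 1.0 / 123)

    classes = np.array(taxonomy.ids)
    uni = Uniform("random_forest", classes)
    X = np.zeros((40, 19))
    y = np.array(taxonomy.ids[:40])
    rep = cl.evaluate(uni, X, y)
    assert rep.multiclass_log_gain == pytest.approx(np.log(123), rel=1e-9)
    assert rep.accuracy <= 1.0 / 40 + 1e-9  # argmax ties -> lowest id

    det = cl.train_classifier(None, classes, "deterministic",
                              taxonomy=taxonomy)
    W = np.zeros((10, 19))
    W[:, :4] = np.vstack([taxonomy.witness(pid)
                          for pid in taxonomy.ids[:10]])
    rep2 = cl.evaluate(det, W, np.array(taxonomy.ids[:10]))
    assert rep2.multiclass_log_gain == pytest.approx(0.0, abs=1e-12)
    assert rep2.accuracy == 1.0


def test_evaluate_input_validation(rf_model):
    with pytest.raises(cl.ClassifierError, match="empty"):
        cl.evaluate(rf_model, np.zeros((0, 19)), np.array([]))
    with pytest.raises(cl.ClassifierError, match="outside"):
        cl.evaluate(rf_model, np.zeros((1, 19)), np.array([999]))


def test_compare_models_self_comparison_is_identical(
        rf_model, test_features_by_regime):
    X, y = test_features_by_regime[4.0]
    table = cl.compare_models({"a": rf_model, "b": rf_model},
                              {"low": (X.iloc[:200], y[:200])})
    a = table[table["model"] == "a"].drop(columns="model").reset_index(
        drop=True)
    b = table[table["model"] == "b"].drop(columns="model").reset_index(
        drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_model_round_trip(tmp_path, rf_model, test_features_by_regime,
                          taxonomy):
    path = tmp_path / "model.joblib"
    cl.save_model(rf_model, path)
    back = cl.load_model(path, taxonomy=taxonomy)
    X, _ = test_features_by_regime[4.0]
    np.testing.assert_array_equal(back.predict_proba(X.iloc[:50]),
                                  rf_model.predict_proba(X.iloc[:50]))


def test_noise_monotonicity_and_baseline_ordering(
        taxonomy, rf_model, training_features, test_features_by_regime):
    """Mean accuracy does not increase with noise, and the probabilistic
    forest beats the deterministic matcher at high noise."""
    accs = {}
    for regime, (X, y) in test_features_by_regime.items():
        accs[regime] = cl.evaluate(rf_model, X, y).accuracy
    assert accs[4.0] >= accs[2.5] >= accs[2.0]
    det = cl.train_classifier(None, np.array(taxonomy.ids),
                              "deterministic", taxonomy=taxonomy)
    X2, y2 = test_features_by_regime[2.0]
    det_rep = cl.evaluate(det, X2, y2)
    assert accs[2.0] >= det_rep.accuracy
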