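"""Probabilistic classification of gene responses onto the profile taxonomy.

The primary model is a Random Forest (200 trees, sqrt-features per split,
leaves of at least twenty instances for bounded memory and smoother
probabilities, class probabilities as tree-vote fractions) trained on
simulated instances
of every taxonomy profile across the three noise regimes.  A Linear
Discriminant Analysis model and the deterministic relation matcher serve as
baselines for model comparison.  All models expose the same interface:
``predict_proba`` returns a probability vector over the taxonomy classes
(summing to one, fixed class order), ``predict`` the argmax id and its
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import joblib
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .features import FEATURE_COLUMNS, FEATURE_SCHEMA_VERSION
from .taxonomy import Taxonomy

MODEL_KINDS = ("random_forest", "lda", "deterministic")

#: probability floor applied inside the multiclass log gain
LOG_GAIN_FLOOR = 1e-15

RF_DEFAULTS = {"n_estimators": 200, "max_features": "sqrt",
               "min_samples_leaf": 20}

#: default tie-snapping tolerance of the deterministic matcher on noisy
#: means (half the minimum simulated signal)
MATCHER_TOLERANCE = 0.25


class ClassifierError(ValueError):
    pass


def _as_matrix(features) -> np.ndarray:
    """Validate the feature schema and return a finite design matrix."""
    if isinstance(features, pd.DataFrame):
        if list(features.columns) != list(FEATURE_COLUMNS):
            raise ClassifierError("feature schema mismatch: expected "
                                  f"columns {list(FEATURE_COLUMNS)}")
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None]
        if X.shape[1] != len(FEATURE_COLUMNS):
            raise ClassifierError("feature schema mismatch: expected "
                                  f"{len(FEATURE_COLUMNS)} columns")
    # infinite t statistics arise from zero-variance degenerate genes
    return np.nan_to_num(X, nan=0.0, posinf=1e6, neginf=-1e6)


@dataclass
class TrainedClassifier:
    """A fitted model plus its class order and training metadata."""

    model_kind: str
    classes: np.ndarray
    feature_schema_version: str = FEATURE_SCHEMA_VERSION
    metadata: dict = field(default_factory=dict)
    _impl: object = None
    _taxonomy: Taxonomy | None = None
    _tolerance: float = MATCHER_TOLERANCE

    def predict_proba(self, features) -> np.ndarray:
        X = _as_matrix(features)
        if self.model_kind == "deterministic":
            probs = np.zeros((len(X), len(self.classes)))
            index = {c: i for i, c in enumerate(self.classes)}
            for row, x in enumerate(X):
                pid = self._taxonomy.match(x[:4], tolerance=self._tolerance)
                probs[row, index[pid]] = 1.0
            return probs
        raw = self._impl.predict_proba(X)
        # sklearn orders columns by its own classes_; realign to ours
        order = np.searchsorted(self.classes, self._impl.classes_)
        probs = np.zeros((len(X), len(self.classes)))
        probs[:, order] = raw
        return probs

    def predict(self, features) -> tuple[np.ndarray, np.ndarray]:
        """(predicted profile ids, probability of the predicted class).

        Ties in the probability vector resolve to the lowest profile id.
        """
        probs = self.predict_proba(features)
        idx = probs.argmax(axis=1)  # argmax takes the first (lowest id) max
        return self.classes[idx], probs[np.arange(len(probs)), idx]


def train_classifier(features, labels, model_kind: str = "random_forest",
                     hyperparams: Mapping | None = None, seed: int = 0,
                     taxonomy: Taxonomy | None = None,
                     metadata: Mapping | None = None) -> TrainedClassifier:
    """Fit a classifier mapping feature vectors to profile ids.

    When a taxonomy is supplied, the class set is its full id list and
    training fails if any profile has no instances (or labels fall outside
    the taxonomy); otherwise classes are the observed labels.  Deterministic
    given the seed.
    """
    if model_kind not in MODEL_KINDS:
        raise ClassifierError(f"unknown model kind {model_kind!r}")
    y = np.asarray(labels)
    if taxonomy is not None:
        valid = set(taxonomy.ids)
        bad = sorted(set(y) - valid)
        if bad:
            raise ClassifierError(f"labels contain unknown profile ids {bad}")
        missing = sorted(valid - set(y))
        if missing and model_kind != "deterministic":
            raise ClassifierError(
                f"no training instances for profile ids {missing}")
        classes = np.array(sorted(valid))
    else:
        classes = np.unique(y)
    meta = dict(metadata or {})
    meta.setdefault("seed", seed)
    meta["model_kind"] = model_kind
    if model_kind == "deterministic":
        if taxonomy is None:
            raise ClassifierError("deterministic matcher requires a taxonomy")
        tol = dict(hyperparams or {}).get("tolerance", MATCHER_TOLERANCE)
        return TrainedClassifier(model_kind, classes, metadata=meta,
                                 _taxonomy=taxonomy, _tolerance=tol)
    X = _as_matrix(features)
    if len(X) != len(y):
        raise ClassifierError("features and labels differ in length")
    if model_kind == "random_forest":
        params = dict(RF_DEFAULTS)
        params.update(hyperparams or {})
        impl = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    else:
        impl = LinearDiscriminantAnalysis(**dict(hyperparams or {}))
    impl.fit(X, y)
    return TrainedClassifier(model_kind, classes, metadata=meta, _impl=impl)


def predict_proba(model: TrainedClassifier, features) -> np.ndarray:
    return model.predict_proba(features)


def predict(model: TrainedClassifier, features):
    return model.predict(features)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationReport:
    """Per-class and aggregate test-set performance."""

    classes: np.ndarray
    accuracy: float
    macro_accuracy: float
    per_class_accuracy: pd.Series
    multiclass_log_gain: float
    precision: pd.Series
    recall: pd.Series
    confusion: pd.DataFrame

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_accuracy": self.macro_accuracy,
            "log_gain": self.multiclass_log_gain,
            "precision_mean": float(self.precision.mean()),
            "recall_mean": float(self.recall.mean()),
        }


def evaluate(model: TrainedClassifier, features, labels) -> EvaluationReport:
    """Accuracy, per-class precision/recall and multiclass log gain.

    Log gain is the mean over instances of -ln(probability assigned to the
    true class), floored at 1e-15; zero for perfect one-hot predictions and
    ln(K) for uniform probabilities over K classes.
    """
    y = np.asarray(labels)
    if y.size == 0:
        raise ClassifierError("empty test set")
    bad = sorted(set(y) - set(model.classes.tolist()))
    if bad:
        raise ClassifierError(f"test labels outside the class set: {bad}")
    probs = model.predict_proba(features)
    idx = probs.argmax(axis=1)
    pred = model.classes[idx]
    class_index = {c: i for i, c in enumerate(model.classes)}
    p_true = probs[np.arange(len(y)), [class_index[c] for c in y]]
    log_gain = float(-np.log(np.maximum(p_true, LOG_GAIN_FLOOR)).mean())

    present = np.unique(y)
    per_class = pd.Series(
        {c: float((pred[y == c] == c).mean()) for c in present})
    prec, rec, _, _ = precision_recall_fscore_support(
        y, pred, labels=present, zero_division=0)
    conf = pd.DataFrame(
        confusion_matrix(y, pred, labels=model.classes),
        index=model.classes, columns=model.classes)
    return EvaluationReport(
        classes=model.classes,
        accuracy=float((pred == y).mean()),
        macro_accuracy=float(per_class.mean()),
        per_class_accuracy=per_class,
        multiclass_log_gain=log_gain,
        precision=pd.Series(prec, index=present),
        recall=pd.Series(rec, index=present),
        confusion=conf,
    )


def compare_models(models: Mapping[str, TrainedClassifier],
                   test_sets: Mapping) -> pd.DataFrame:
    """Per-(model, regime) table of accuracy, log gain and precision/recall.

    ``test_sets`` maps a regime label to a (features, labels) pair shared
    by all models.
    """
    rows = []
    for regime, (features, labels) in test_sets.items():
        for name, model in models.items():
            rep = evaluate(model, features, labels)
            rows.append({"model": name, "regime": regime, **rep.summary()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence


def save_model(model: TrainedClassifier, path) -> None:
    payload = {
        "model_kind": model.model_kind,
        "classes": model.classes,
        "feature_schema_version": model.feature_schema_version,
        "metadata": model.metadata,
        "impl": model._impl,
        "tolerance": model._tolerance,
    }
    joblib.dump(payload, path)


def load_model(path, taxonomy: Taxonomy | None = None) -> TrainedClassifier:
    payload = joblib.load(path)
    if payload["feature_schema_version"] != FEATURE_SCHEMA_VERSION:
        raise ClassifierError("feature schema version mismatch")
    return TrainedClassifier(
        model_kind=payload["model_kind"], classes=payload["classes"],
        feature_schema_version=payload["feature_schema_version"],
        metadata=payload["metadata"], _impl=payload["impl"],
        _taxonomy=taxonomy, _tolerance=payload["tolerance"])
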