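"""Classical fingerprint-based classifiers behind one fit/predict surface.

Eight algorithms are wrapped: one-vs-rest logistic regression (a
separate binary discriminator per class, prediction by maximum score),
k-nearest neighbours, a single decision tree, a random forest, Gaussian
naive Bayes, linear discriminant analysis, and support vector machines
with linear, RBF and sigmoid kernels.  All operate on fixed-length
fingerprint vectors and emit exactly one predicted class per molecule —
they never abstain.  Hyper-parameters default to the underlying
scikit-learn defaults unless overridden in the spec; every stochastic
algorithm is keyed to the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ALGORITHMS",
    "SVM_KERNELS",
    "ClassifierSpec",
    "TrainedModel",
    "train_classical",
    "predict_classical",
    "save_model",
    "load_model",
]

ALGORITHMS = ("LR", "KNN", "CART", "RF", "NB", "LDA", "SVM")
SVM_KERNELS = ("linear", "rbf", "sigmoid")


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm choice plus hyper-parameters and seed.

    ``kernel`` applies only to SVM; ``hyperparameters`` are passed
    through to the underlying estimator (e.g. ``n_neighbors`` for KNN,
    ``n_estimators`` for RF).
    """

    algorithm: str
    kernel: str | None = None
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if self.algorithm == "SVM":
            if self.kernel not in SVM_KERNELS:
                raise ValueError(
                    f"SVM requires a kernel from {SVM_KERNELS}, got {self.kernel!r}"
                )
        elif self.kernel is not None:
            raise ValueError("kernel may only be set for the SVM algorithm")
        k = self.hyperparameters.get("n_neighbors")
        if k is not None and k < 1:
            raise ValueError("n_neighbors must be >= 1")


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "LR":
        # one-vs-rest: one binary discriminator per class, argmax decides
        base = LogisticRegression(max_iter=hp.pop("max_iter", 1000), **hp)
        return OneVsRestClassifier(base)
    if spec.algorithm == "KNN":
        return KNeighborsClassifier(**hp)
    if spec.algorithm == "CART":
        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    if spec.algorithm == "RF":
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.algorithm == "NB":
        return GaussianNB(**hp)
    if spec.algorithm == "LDA":
        return LinearDiscriminantAnalysis(**hp)
    if spec.algorithm == "SVM":
        return SVC(kernel=spec.kernel, random_state=spec.seed, **hp)
    raise AssertionError("unreachable")


@dataclass
class TrainedModel:
    """A fitted estimator with its class-label order and input width."""

    spec: ClassifierSpec
    classes: list[str]
    estimator: Any
    n_features: int


def train_classical(
    spec: ClassifierSpec, X: np.ndarray, y: list[str]
) -> TrainedModel:
    """Fit the specified algorithm on fingerprint rows X with labels y.

    Requires at least two distinct labels and matching |X| = |y|.
    Deterministic given the spec's seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("X must be a non-empty 2-D array of fingerprints")
    if len(X) != len(y):
        raise ValueError(f"length mismatch: {len(X)} vectors vs {len(y)} labels")
    labels = sorted(set(y))
    if len(labels) < 2:
        raise ValueError("training requires at least two distinct class labels")
    estimator = _build_estimator(spec)
    estimator.fit(X, np.asarray(y))
    return TrainedModel(
        spec=spec,
        classes=list(estimator.classes_),
        estimator=estimator,
        n_features=X.shape[1],
    )


def predict_classical(model: TrainedModel, X: np.ndarray) -> list[str]:
    """One predicted class per input row; never abstains.

    Argmax ties (possible for the one-vs-rest discriminators) resolve
    to the first class in sorted label order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected vectors of length {model.n_features}, "
            f"got shape {X.shape}"
        )
    return [str(label) for label in model.estimator.predict(X)]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model; round-trips through :func:`load_model`."""
    joblib.dump(model, path)


def load_model(path: str | Path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise TypeError(f"{path} does not contain a TrainedModel")
    return model


def write_predictions_tsv(
    member_ids: list[str], predictions: list[str], path: str | Path
) -> None:
    """TSV export: member_id, predicted_class_id."""
    with open(path, "w") as fh:
        fh.write("member_id\tpredicted_class_id\n")
        for mid, pred in zip(member_ids, predictions, strict=True):
            fh.write(f"{mid}\t{pred}\n")
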