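"""Classifier harness for kinematic feature vectors.

Each animal is one point in feature space (any subset of F1-F4); a
classifier partitions the space into one decision region per damage
class.  Ten classical classifiers are supported — minimum (Euclidean)
distance to class means, LDA, QDA, Mahalanobis distance, KNN with 1/3/5
neighbors, linear and RBF SVMs, and a shallow one-hidden-layer neural
network — evaluated with stratified 10-fold cross-validation repeated
ten times, reporting mean and standard deviation of the fold accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIER_NAMES",
    "FeatureDataset",
    "CVResult",
    "MahalanobisClassifier",
    "make_classifier",
    "train_classifier",
    "predict",
    "cross_validate",
    "plot_decision_regions",
]

CLASSIFIER_NAMES = (
    "mindist",
    "lda",
    "qda",
    "knn1",
    "knn3",
    "knn5",
    "mahalanobis",
    "svm-linear",
    "svm-rbf",
    "nnet",
)

DEFAULT_FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "f1-f2": ("f1", "f2"),
    "f3-f4": ("f3", "f4"),
    "all": ("f1", "f2", "f3", "f4"),
}


@dataclass
class FeatureDataset:
    """Labeled feature vectors: one row per animal/video."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) matching y")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")
        if np.isnan(self.X).any():
            raise ValueError("selected features contain missing values")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def select(self, names: Sequence[str]) -> "FeatureDataset":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureDataset(self.X[:, idx], self.y, tuple(names))

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, feature_names: Sequence[str], label_column: str = "label"
    ) -> "FeatureDataset":
        return cls(
            df[list(feature_names)].to_numpy(dtype=float),
            df[label_column].to_numpy(),
            tuple(feature_names),
        )


@dataclass
class CVResult:
    """Cross-validation summary for one (classifier, feature set) pair.

    ``fold_accuracies`` has shape (n_repeats, n_folds); ``mean_accuracy``
    is the grand mean of all fold accuracies and ``std_accuracy`` their
    standard deviation.
    """

    classifier_name: str
    feature_set: tuple[str, ...]
    fold_accuracies: np.ndarray
    n_repeats: int
    seed: int
    mean_accuracy: float = field(init=False)
    std_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        acc = np.asarray(self.fold_accuracies, dtype=float)
        if ((acc < 0) | (acc > 1)).any():
            raise ValueError("fold accuracies must lie in [0, 1]")
        self.fold_accuracies = acc
        self.mean_accuracy = float(acc.mean())
        self.std_accuracy = float(acc.std(ddof=0))

    def __str__(self) -> str:  # Table-1-style cell
        return f"{100 * self.mean_accuracy:.1f} +- {100 * self.std_accuracy:.1f}"


class MahalanobisClassifier(ClassifierMixin, BaseEstimator):
    """Minimum Mahalanobis distance to the class means.

    Each class contributes its own mean and covariance (ridge-regularized
    so near-degenerate classes remain invertible); a sample is assigned
    to the class whose Mahalanobis distance is smallest, ties breaking
    toward the lower class index.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.means_ = []
        self.precisions_ = []
        d = X.shape[1]
        for cls in self.classes_:
            sub = X[y == cls]
            self.means_.append(sub.mean(axis=0))
            cov = np.cov(sub, rowvar=False) if len(sub) > 1 else np.eye(d)
            cov = np.atleast_2d(cov) + self.ridge * np.eye(d)
            self.precisions_.append(np.linalg.inv(cov))
        return self

    def _distances(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.classes_)))
        for k, (mu, prec) in enumerate(zip(self.means_, self.precisions_)):
            diff = X - mu
            out[:, k] = np.einsum("ij,jk,ik->i", diff, prec, diff)
        return out

    def predict(self, X):
        return self.classes_[np.argmin(self._distances(X), axis=1)]


def make_classifier(kind: str, seed: int = 0, standardize: bool = True, **hyperparams):
    """Instantiate one of the supported classifiers by name.

    When ``standardize`` is True the estimator is wrapped in a pipeline
    that z-scores features on the training folds only, so degree-valued
    ranges and unit-interval correlations are comparable for
    distance-based classifiers.
    """
    kind = kind.lower()
    if kind == "mindist":
        est = NearestCentroid(**hyperparams)
    elif kind == "lda":
        est = LinearDiscriminantAnalysis(**hyperparams)
    elif kind == "qda":
        # mild covariance regularization keeps QDA solvable when a class's
        # features are nearly collinear (common on clean synthetic cohorts)
        est = QuadraticDiscriminantAnalysis(**{"reg_param": 1e-3, **hyperparams})
    elif kind in {"knn1", "knn3", "knn5"}:
        est = KNeighborsClassifier(n_neighbors=int(kind[-1]), **hyperparams)
    elif kind == "mahalanobis":
        est = MahalanobisClassifier(**hyperparams)
    elif kind == "svm-linear":
        est = SVC(kernel="linear", C=hyperparams.pop("C", 1.0), **hyperparams)
    elif kind == "svm-rbf":
        est = SVC(kernel="rbf", C=hyperparams.pop("C", 1.0), gamma=hyperparams.pop("gamma", "scale"), **hyperparams)
    elif kind == "nnet":
        est = MLPClassifier(
            hidden_layer_sizes=hyperparams.pop("hidden_layer_sizes", (10,)),
            max_iter=hyperparams.pop("max_iter", 2000),
            random_state=seed,
            **hyperparams,
        )
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_NAMES}")
    if standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def train_classifier(
    data: FeatureDataset, kind: str, seed: int = 0, standardize: bool = True, **hyperparams
):
    """Fit a classifier on the full dataset and return the trained model."""
    if len(data.classes) < 2:
        raise ValueError("training requires at least two classes")
    model = make_classifier(kind, seed=seed, standardize=standardize, **hyperparams)
    model.fit(data.X, data.y)
    return model


def predict(model, features: np.ndarray) -> np.ndarray:
    """Predict class labels for one or more feature vectors."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    n_expected = getattr(model, "n_features_in_", None)
    if n_expected is not None and X.shape[1] != n_expected:
        raise ValueError(f"feature dimension {X.shape[1]} != training dimension {n_expected}")
    return model.predict(X)


def cross_validate(
    data: FeatureDataset,
    kind: str,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    standardize: bool = True,
    **hyperparams,
) -> CVResult:
    """Repeated stratified k-fold accuracy of one classifier.

    Folds are stratified so each test fold holds roughly equal class
    proportions (about 3 per class for the standard 90-animal cohort);
    each repeat reshuffles the fold assignment deterministically from
    ``seed``.  Every sample is tested exactly once per repeat.
    """
    counts = pd.Series(data.y).value_counts()
    if (counts < n_folds).any():
        raise ValueError(
            f"every class needs at least n_folds={n_folds} members; got {counts.to_dict()}"
        )
    splitter = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats, random_state=int(seed) & 0x7FFFFFFF)
    accs = []
    for train_idx, test_idx in splitter.split(data.X, data.y):
        model = make_classifier(kind, seed=seed, standardize=standardize, **hyperparams)
        model.fit(data.X[train_idx], data.y[train_idx])
        accs.append(float(np.mean(model.predict(data.X[test_idx]) == data.y[test_idx])))
    return CVResult(
        classifier_name=kind,
        feature_set=data.feature_names,
        fold_accuracies=np.asarray(accs).reshape(n_repeats, n_folds),
        n_repeats=n_repeats,
        seed=seed,
    )


def comparison_table(
    data: FeatureDataset,
    classifiers: Sequence[str] = CLASSIFIER_NAMES,
    feature_sets: dict[str, Sequence[str]] | None = None,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> pd.DataFrame:
    """Classifier x feature-set accuracy table (``mean +- std`` cells)."""
    feature_sets = feature_sets or DEFAULT_FEATURE_SETS
    table: dict[str, dict[str, str]] = {}
    for set_name, names in feature_sets.items():
        sub = data.select(names)
        for kind in classifiers:
            res = cross_validate(sub, kind, n_folds=n_folds, n_repeats=n_repeats, seed=seed, standardize=standardize)
            table.setdefault(kind, {})[set_name] = str(res)
    return pd.DataFrame(table).T.rename_axis("classifier")


def plot_decision_regions(model, data: FeatureDataset, ax=None, resolution: int = 200):
    """Decision regions of a trained model over a 2D feature space."""
    if data.X.shape[1] != 2:
        raise ValueError("decision-region plots require exactly two features")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    (x0, y0), (x1, y1) = data.X.min(axis=0), data.X.max(axis=0)
    mx, my = 0.1 * (x1 - x0) + 1e-6, 0.1 * (y1 - y0) + 1e-6
    xx, yy = np.meshgrid(
        np.linspace(x0 - mx, x1 + mx, resolution), np.linspace(y0 - my, y1 + my, resolution)
    )
    classes = list(data.classes)
    zz = np.array(
        [classes.index(c) for c in model.predict(np.column_stack([xx.ravel(), yy.ravel()]))]
    ).reshape(xx.shape)
    ax.contourf(xx, yy, zz, levels=len(classes), alpha=0.25, cmap="viridis")
    for cls in classes:
        sel = data.y == cls
        ax.scatter(data.X[sel, 0], data.X[sel, 1], s=14, label=str(cls))
    ax.set_xlabel(data.feature_names[0])
    ax.set_ylabel(data.feature_names[1])
    ax.legend(fontsize=8)
    return ax
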