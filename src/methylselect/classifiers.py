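"""Uniform fit/predict contract over the classifier families used in selection.

Families: k-nearest neighbors (Euclidean), decision tree, kernel-density
naive Bayes, and linear / Gaussian-kernel SVMs.  KNN and the kernel naive
Bayes are implemented here so that tie-breaking and bandwidth handling are
fully specified; trees and SVMs delegate to scikit-learn.

Determinism contract: predictions are a function of the (unordered)
training set, the spec and the seed.  KNN distance ties are broken by a
stable sort on (distance, sample_id), and even vote ties fall back to the
single nearest neighbor's label.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core import DegenerateTrainingError

FAMILIES = ("knn", "decision_tree", "naive_bayes", "svm_linear", "svm_gaussian")


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyper-parameters for one classifier family.

    ``min_parent``/``min_leaf`` follow the decision-tree convention of a
    minimum node size to attempt a split (10) and a minimum leaf size (1).
    ``nb_bandwidth_floor`` keeps the kernel-density estimate proper on
    constant features (units: beta values).
    """

    family: str = "knn"
    k_neighbors: int = 1
    min_parent: int = 10
    min_leaf: int = 1
    class_weights: Optional[Mapping[str, float]] = None
    nb_bandwidth_floor: float = 1e-3
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.k_neighbors < 1 or self.k_neighbors % 2 == 0:
            raise ValueError("k_neighbors must be a positive odd integer")
        if self.class_weights is not None:
            if any(w <= 0 for w in self.class_weights.values()):
                raise ValueError("class weights must be positive")


@dataclass
class FittedClassifier:
    spec: ClassifierSpec
    n_features: int
    classes: list[str]
    _state: dict = field(default_factory=dict, repr=False)


def _silverman_bandwidths(x: np.ndarray, floor: float) -> np.ndarray:
    """Per-feature Silverman rule-of-thumb bandwidths, floored."""
    n = x.shape[0]
    sd = x.std(axis=0, ddof=1) if n > 1 else np.zeros(x.shape[1])
    iqr = np.subtract(*np.percentile(x, [75, 25], axis=0))
    spread = np.where(iqr > 0, np.minimum(sd, iqr / 1.349), sd)
    h = 0.9 * spread * n ** (-1 / 5)
    return np.maximum(h, floor)


def fit(
    spec: ClassifierSpec,
    train_features: np.ndarray,
    train_labels: Sequence[str],
    sample_ids: Optional[Sequence] = None,
) -> FittedClassifier:
    """Fit one classifier; deterministic given spec, data and sample ids.

    Training rows are canonicalized by sorting on ``sample_ids`` so that
    permuting input order never changes the fitted model.
    """
    x = np.asarray(train_features, dtype=float)
    if x.ndim != 2:
        x = x.reshape(len(train_labels), -1)
    y = np.asarray(train_labels, dtype=object)
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on sample count")
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    ids = np.arange(x.shape[0]) if sample_ids is None else np.asarray(sample_ids)
    order = np.argsort(ids, kind="stable")
    x, y, ids = x[order], y[order], ids[order]

    classes = sorted(set(y))
    if spec.family in ("svm_linear", "svm_gaussian") and len(classes) < 2:
        raise DegenerateTrainingError(
            f"{spec.family} requires two classes; got {classes}"
        )

    model = FittedClassifier(spec=spec, n_features=x.shape[1], classes=classes)
    st = model._state
    if spec.family == "knn":
        st["x"], st["y"] = x, y
    elif spec.family == "decision_tree":
        tree = DecisionTreeClassifier(
            criterion="gini",
            min_samples_split=spec.min_parent,
            min_samples_leaf=spec.min_leaf,
            random_state=spec.seed,
        )
        tree.fit(x, y)
        st["tree"] = tree
    elif spec.family == "naive_bayes":
        per_class = {}
        n = x.shape[0]
        for c in classes:
            xc = x[y == c]
            per_class[c] = {
                "x": xc,
                "log_prior": np.log(xc.shape[0] / n),
                "h": _silverman_bandwidths(xc, spec.nb_bandwidth_floor),
            }
        st["per_class"] = per_class
    else:
        kernel = "linear" if spec.family == "svm_linear" else "rbf"
        svc = SVC(
            kernel=kernel,
            C=spec.svm_c,
            gamma="scale",
            class_weight=dict(spec.class_weights) if spec.class_weights else None,
            random_state=spec.seed,
        )
        svc.fit(x, y)
        st["svc"] = svc
    return model


def _knn_predict(model: FittedClassifier, x: np.ndarray) -> np.ndarray:
    tx, ty = model._state["x"], model._state["y"]
    k = min(model.spec.k_neighbors, tx.shape[0])
    d = cdist(x, tx)
    out = np.empty(x.shape[0], dtype=object)
    for i in range(x.shape[0]):
        # rows are pre-sorted by sample_id, so a stable sort on distance
        # yields the (distance, sample_id) order
        nn = np.argsort(d[i], kind="stable")[:k]
        votes: dict[str, int] = {}
        for j in nn:
            votes[ty[j]] = votes.get(ty[j], 0) + 1
        best = max(votes.values())
        winners = [c for c, v in votes.items() if v == best]
        out[i] = winners[0] if len(winners) == 1 else ty[nn[0]]
    return out


def _nb_predict(model: FittedClassifier, x: np.ndarray) -> np.ndarray:
    per_class = model._state["per_class"]
    scores = np.empty((x.shape[0], len(model.classes)))
    for ci, c in enumerate(model.classes):
        info = per_class[c]
        xc, h = info["x"], info["h"]
        total = np.full(x.shape[0], info["log_prior"])
        for j in range(x.shape[1]):
            z = (x[:, None, j] - xc[None, :, j]) / h[j]
            log_dens = (
                logsumexp(-0.5 * z * z, axis=1)
                - np.log(xc.shape[0])
                - np.log(h[j] * np.sqrt(2 * np.pi))
            )
            total += log_dens
        scores[:, ci] = total
    # argmax ties resolve to the first class in sorted order
    return np.asarray(model.classes, dtype=object)[scores.argmax(axis=1)]


def predict(model: FittedClassifier, test_features: np.ndarray) -> np.ndarray:
    """One label per test row; deterministic."""
    x = np.asarray(test_features, dtype=float)
    if x.ndim == 1:
        x = x.reshape(1, -1)
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {x.shape[1]} != training dimension "
            f"{model.n_features}"
        )
    fam = model.spec.family
    if fam == "knn":
        return _knn_predict(model, x)
    if fam == "naive_bayes":
        return _nb_predict(model, x)
    if fam == "decision_tree":
        return model._state["tree"].predict(x).astype(object)
    return model._state["svc"].predict(x).astype(object)


def misclassification_count(
    model: FittedClassifier,
    test_features: np.ndarray,
    test_labels: Sequence[str],
) -> int:
    """Number of test samples whose predicted label mismatches the truth."""
    pred = predict(model, test_features)
    return int(np.sum(pred != np.asarray(test_labels, dtype=object)))
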