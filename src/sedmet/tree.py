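"""Binary CART with Gini-impurity splitting, plus the fixed posture tree.

The learned trees here are deliberately small (default depth <= 5, leaf
size >= 5): the calibration philosophy is that a shallow, human-readable
decision tree over well-chosen signal features beats an opaque model that
nobody can re-implement from a figure.

The posture classifier is not learned at run time at all: it is the fixed
three-node rule over the 5th and 95th percentile of the thigh accelerometer's
longitudinal (y) axis.  Sitting requires a thigh more horizontal than 39 deg
from vertical during 95% of the minute (5th percentile >= -0.774 g under the
standing-reads--1 g convention); walking is recognised by per-step
acceleration/deceleration excursions beyond the quiet-standing band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

SITTING, STANDING, WALKING = "sitting", "standing", "walking"


@dataclass
class TreeConfig:
    """Complexity limits for learned MET trees."""

    max_depth: int = 5
    min_leaf: int = 5

    def __post_init__(self):
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


class TreeNode:
    """Internal node (feature index + threshold) or leaf (class counts)."""

    __slots__ = ("feature", "threshold", "left", "right", "counts")

    def __init__(self, *, feature=None, threshold=None, left=None, right=None,
                 counts=None):
        self.feature = feature
        self.threshold = threshold
        self.left = left
        self.right = right
        self.counts = counts

    @property
    def is_leaf(self) -> bool:
        return self.counts is not None


def gini_impurity(counts: np.ndarray) -> float:
    """Gini diversity index 1 - sum(p_k^2) of a class-count vector."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split_feature(x: np.ndarray, y_onehot: np.ndarray, min_leaf: int):
    """Best (threshold, impurity_decrease) for one feature, or None.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; among equal decreases the lowest threshold wins (first argmax
    over ascending candidates).
    """
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    cum = np.cumsum(y_onehot[order], axis=0)  # (n, k) class counts left of cut
    n = x.size
    total = cum[-1]
    parent = gini_impurity(total)

    boundary = np.flatnonzero(xs[:-1] < xs[1:])  # split after position i
    if boundary.size == 0:
        return None
    n_left = boundary + 1
    n_right = n - n_left
    ok = (n_left >= min_leaf) & (n_right >= min_leaf)
    if not ok.any():
        return None
    boundary = boundary[ok]
    n_left, n_right = n_left[ok], n_right[ok]

    left_counts = cum[boundary]
    right_counts = total - left_counts
    gini_left = 1.0 - np.sum((left_counts / n_left[:, None]) ** 2, axis=1)
    gini_right = 1.0 - np.sum((right_counts / n_right[:, None]) ** 2, axis=1)
    decrease = parent - (n_left * gini_left + n_right * gini_right) / n

    k = int(np.argmax(decrease))
    threshold = 0.5 * (xs[boundary[k]] + xs[boundary[k] + 1])
    return float(threshold), float(decrease[k])


class GiniTreeClassifier(ClassifierMixin, BaseEstimator):
    """Greedy recursive-partitioning classification tree (Gini criterion).

    At every node the search is exhaustive over all features and all
    midpoints between consecutive sorted distinct values; the split with the
    largest Gini impurity decrease is taken.  Ties break toward the lower
    feature index, then the lower threshold.  Growth stops on node purity,
    the ``min_leaf`` occupancy bound, or ``max_depth``.

    Samples with feature value < threshold go left.  ``predict_proba`` returns
    training-class fractions at the reached leaf, which is what ROC analysis
    downstream consumes.
    """

    def __init__(self, max_depth: int = 5, min_leaf: int = 5):
        self.max_depth = max_depth
        self.min_leaf = min_leaf

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y):
        X, names = _as_matrix(X)
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise ValueError("cannot fit a tree on empty data")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes to fit")
        self.feature_names_in_ = names
        self.n_features_in_ = X.shape[1]
        onehot = np.eye(self.classes_.size, dtype=np.int64)[y_idx]
        self.tree_ = self._grow(X, onehot, depth=0)
        self.used_features_ = tuple(
            names[i] for i in sorted(_used_feature_indices(self.tree_))
        )
        return self

    def _grow(self, X: np.ndarray, onehot: np.ndarray, depth: int) -> TreeNode:
        counts = onehot.sum(axis=0)
        if (
            depth >= self.max_depth
            or np.count_nonzero(counts) < 2
            or X.shape[0] < 2 * self.min_leaf
        ):
            return TreeNode(counts=counts)
        best = None  # (decrease, feature, threshold)
        for j in range(X.shape[1]):
            found = _best_split_feature(X[:, j], onehot, self.min_leaf)
            if found is None:
                continue
            threshold, decrease = found
            if best is None or decrease > best[0]:
                best = (decrease, j, threshold)
        if best is None or best[0] <= 0:
            return TreeNode(counts=counts)
        _, j, threshold = best
        mask = X[:, j] < threshold
        return TreeNode(
            feature=j,
            threshold=threshold,
            left=self._grow(X[mask], onehot[mask], depth + 1),
            right=self._grow(X[~mask], onehot[~mask], depth + 1),
        )

    # -- prediction -------------------------------------------------------
    def _leaf_counts(self, X) -> np.ndarray:
        X = self._validate_predict_input(X)
        out = np.empty((X.shape[0], self.classes_.size), dtype=float)
        for i in range(X.shape[0]):
            node = self.tree_
            while not node.is_leaf:
                node = node.left if X[i, node.feature] < node.threshold else node.right
            out[i] = node.counts
        return out

    def _validate_predict_input(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            used = set(_used_feature_indices(self.tree_))
            missing = [
                self.feature_names_in_[i]
                for i in used
                if self.feature_names_in_[i] not in X.columns
            ]
            if missing:
                raise ValueError(f"input lacks split feature(s): {missing}")
            X = X.reindex(columns=list(self.feature_names_in_)).to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"expected {self.n_features_in_} features, got {X.shape[1]}"
                )
        return X

    def predict_proba(self, X) -> np.ndarray:
        counts = self._leaf_counts(X)
        return counts / counts.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self._leaf_counts(X), axis=1)]

    def predict_score(self, X, positive_class=None) -> np.ndarray:
        """Positive-class fraction at the reached leaf, in [0, 1]."""
        proba = self.predict_proba(X)
        if positive_class is None:
            if self.classes_.size != 2:
                raise ValueError("positive_class required for non-binary trees")
            positive_class = self.classes_[-1]
        k = int(np.flatnonzero(self.classes_ == positive_class)[0])
        return proba[:, k]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        def node_dict(node: TreeNode):
            if node.is_leaf:
                return {
                    "counts": {
                        str(c): int(n) for c, n in zip(self.classes_, node.counts)
                    }
                }
            return {
                "feature": self.feature_names_in_[node.feature],
                "threshold": node.threshold,
                "left": node_dict(node.left),
                "right": node_dict(node.right),
            }

        return {
            "classes": [str(c) for c in self.classes_],
            "max_depth": self.max_depth,
            "min_leaf": self.min_leaf,
            "features": list(self.feature_names_in_),
            "tree": node_dict(self.tree_),
        }

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "GiniTreeClassifier":
        est = cls(max_depth=payload["max_depth"], min_leaf=payload["min_leaf"])
        est.classes_ = np.asarray(payload["classes"])
        est.feature_names_in_ = tuple(payload["features"])
        est.n_features_in_ = len(est.feature_names_in_)
        name_to_idx = {n: i for i, n in enumerate(est.feature_names_in_)}

        def build(d):
            if "counts" in d:
                counts = np.array(
                    [d["counts"].get(str(c), 0) for c in est.classes_], dtype=np.int64
                )
                return TreeNode(counts=counts)
            return TreeNode(
                feature=name_to_idx[d["feature"]],
                threshold=float(d["threshold"]),
                left=build(d["left"]),
                right=build(d["right"]),
            )

        est.tree_ = build(payload["tree"])
        est.used_features_ = tuple(
            est.feature_names_in_[i] for i in sorted(_used_feature_indices(est.tree_))
        )
        return est

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "GiniTreeClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _used_feature_indices(node: TreeNode) -> set[int]:
    if node.is_leaf:
        return set()
    return (
        {node.feature}
        | _used_feature_indices(node.left)
        | _used_feature_indices(node.right)
    )


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(str(c) for c in X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    return X, tuple(f"x{i}" for i in range(X.shape[1]))


@dataclass(frozen=True)
class PostureThresholds:
    """Thresholds of the fixed posture tree (accelerometer y axis, in g).

    ``sit_threshold`` is the printed sitting rule (5th percentile >= -0.774,
    i.e. a 39-deg thigh angle); the walking thresholds bound the
    quiet-standing band and are configuration calibrated once on synthetic
    data, since no printed values exist for them.
    """

    sit_threshold: float = -0.774
    walk_accel_threshold: float = -1.35
    walk_decel_threshold: float = -0.85

    def __post_init__(self):
        if not self.sit_threshold > self.walk_accel_threshold:
            raise ValueError("sit_threshold must exceed walk_accel_threshold")


class PostureTreeClassifier(ClassifierMixin, BaseEstimator):
    """The fixed three-node minute classifier: sitting / standing / walking.

    Node 1: 5th percentile of accel-y >= sit_threshold -> sitting (thigh more
    horizontal than ~39 deg for 95% of the minute).  Node 2: 5th percentile
    below walk_accel_threshold -> walking (per-step acceleration).  Node 3:
    95th percentile above walk_decel_threshold -> walking (per-step
    deceleration); otherwise standing.

    Operates on the posture feature columns ``accel.y.p5`` / ``accel.y.p95``
    (or a raw minute via :meth:`classify_minute`).
    """

    def __init__(self, sit_threshold: float = -0.774,
                 walk_accel_threshold: float = -1.35,
                 walk_decel_threshold: float = -0.85):
        self.sit_threshold = sit_threshold
        self.walk_accel_threshold = walk_accel_threshold
        self.walk_decel_threshold = walk_decel_threshold

    @property
    def thresholds(self) -> PostureThresholds:
        return PostureThresholds(
            self.sit_threshold, self.walk_accel_threshold, self.walk_decel_threshold
        )

    def fit(self, X=None, y=None):
        self.thresholds  # validates the ordering invariant
        self.classes_ = np.array([SITTING, STANDING, WALKING])
        return self

    def predict(self, X) -> np.ndarray:
        self.fit()
        if isinstance(X, pd.DataFrame):
            p5 = X["accel.y.p5"].to_numpy(dtype=float)
            p95 = X["accel.y.p95"].to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            p5, p95 = X[:, 0], X[:, 1]
        return np.select(
            [
                p5 >= self.sit_threshold,
                p5 < self.walk_accel_threshold,
                p95 > self.walk_decel_threshold,
            ],
            [SITTING, WALKING, WALKING],
            default=STANDING,
        )

    def classify_minute(self, accel_y_minute: np.ndarray) -> str:
        y = np.asarray(accel_y_minute, dtype=float)
        p5, p95 = np.percentile(y, 5), np.percentile(y, 95)
        return str(self.predict([[p5, p95]])[0])


def posture_tree(thresholds: PostureThresholds | None = None) -> PostureTreeClassifier:
    """Build the fixed posture classifier from a threshold set."""
    t = thresholds or PostureThresholds()
    return PostureTreeClassifier(
        sit_threshold=t.sit_threshold,
        walk_accel_threshold=t.walk_accel_threshold,
        walk_decel_threshold=t.walk_decel_threshold,
    ).fit()
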