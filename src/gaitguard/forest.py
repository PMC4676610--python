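"""Vote-counting random forest with deterministic splits and JSON transfer.

The activity classifier is an ensemble of fully grown decision trees, each
trained on a bootstrap resample; every split draws a small random subset of
features (16 of 260 by default) and picks the (feature, threshold) pair that
maximizes entropy-based information gain, with thresholds at midpoints
between consecutive distinct values. The ensemble's class is the majority
vote and its confidence the fraction of trees voting for the winner, which
is why the trees are hand-grown here rather than delegated to an
off-the-shelf ensemble that averages leaf probabilities.

Determinism conventions: split ties are broken toward the lower feature
index, then the lower threshold; vote ties toward the first class in
``classes_`` (alphabetically "sitting" before "walking").
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.utils.validation import check_array, check_X_y

_GAIN_TOL = 1e-12


@dataclass
class ForestConfig:
    """Hyperparameters of the activity forest."""

    n_trees: int = 200
    n_split_candidates: int = 16
    split_criterion: str = "information_gain"
    min_leaf: int = 1
    max_depth: int | None = None
    seed: int = 0
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_split_candidates < 1:
            raise ValueError("n_split_candidates must be >= 1")
        if self.split_criterion != "information_gain":
            raise ValueError(f"unsupported split criterion {self.split_criterion!r}")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass
class Prediction:
    """One ensemble prediction: majority label, vote-fraction confidence."""

    label: str
    confidence: float
    votes: dict


class _Tree:
    """Flat-array decision tree; ``klass[i] < 0`` marks internal nodes."""

    __slots__ = ("feature", "threshold", "left", "right", "klass", "counts")

    def __init__(self, feature, threshold, left, right, klass, counts):
        self.feature = np.asarray(feature, dtype=np.int32)
        self.threshold = np.asarray(threshold, dtype=np.float64)
        self.left = np.asarray(left, dtype=np.int32)
        self.right = np.asarray(right, dtype=np.int32)
        self.klass = np.asarray(klass, dtype=np.int32)
        self.counts = np.asarray(counts, dtype=np.int64)

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(X.shape[0], dtype=np.int32)
        active = np.flatnonzero(self.klass[node] < 0)
        while active.size:
            cur = node[active]
            go_left = X[active, self.feature[cur]] <= self.threshold[cur]
            node[active] = np.where(go_left, self.left[cur], self.right[cur])
            active = active[self.klass[node[active]] < 0]
        return self.klass[node]

    def to_nested(self, i: int = 0) -> dict:
        if self.klass[i] >= 0:
            return {"counts": self.counts[i].tolist(), "class": int(self.klass[i])}
        return {
            "feature": int(self.feature[i]),
            "threshold": float(self.threshold[i]),
            "left": self.to_nested(int(self.left[i])),
            "right": self.to_nested(int(self.right[i])),
        }

    @classmethod
    def from_nested(cls, root: dict, n_classes: int) -> "_Tree":
        feature, threshold, left, right, klass, counts = [], [], [], [], [], []

        def build(node: dict) -> int:
            i = len(feature)
            feature.append(-1)
            threshold.append(0.0)
            left.append(-1)
            right.append(-1)
            if "class" in node:
                klass.append(int(node["class"]))
                counts.append(list(node.get("counts", [0] * n_classes)))
            else:
                klass.append(-1)
                counts.append([0] * n_classes)
                feature[i] = int(node["feature"])
                threshold[i] = float(node["threshold"])
                left[i] = build(node["left"])
                right[i] = build(node["right"])
            return i

        build(root)
        return cls(feature, threshold, left, right, klass, counts)


def _entropy(counts: np.ndarray) -> np.ndarray:
    """Class entropy of count vectors along the last axis, 0 log 0 = 0."""
    n = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, counts / np.where(n > 0, n, 1), 0.0)
        h = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return h.sum(axis=-1)


def best_split(
    X: np.ndarray, y: np.ndarray, idx: np.ndarray, features: np.ndarray, n_classes: int
) -> tuple[int, float, float]:
    """Best (feature, threshold, gain) over candidate features at one node.

    Thresholds are midpoints between consecutive distinct sorted values.
    Ties: lower feature index, then lower threshold. Returns gain <= 0 when
    no split separates the node.
    """
    ys = y[idx]
    total = np.bincount(ys, minlength=n_classes).astype(float)
    n = ys.size
    h_parent = float(_entropy(total))
    best_f, best_t, best_gain = -1, 0.0, 0.0
    for f in np.sort(features):
        v = X[idx, f]
        order = np.argsort(v, kind="stable")
        vs, yo = v[order], ys[order]
        cut = np.flatnonzero(vs[:-1] < vs[1:])
        if cut.size == 0:
            continue
        onehot = yo[:, None] == np.arange(n_classes)[None, :]
        cum = np.cumsum(onehot, axis=0).astype(float)
        left = cum[cut]
        right = total[None, :] - left
        nl = left.sum(axis=1)
        nr = n - nl
        gains = h_parent - (nl * _entropy(left) + nr * _entropy(right)) / n
        k = int(np.argmax(gains))  # first max -> lowest threshold
        if gains[k] > best_gain + _GAIN_TOL:
            best_f = int(f)
            best_t = float((vs[cut[k]] + vs[cut[k] + 1]) / 2.0)
            best_gain = float(gains[k])
    return best_f, best_t, best_gain


class VoteForestClassifier(ClassifierMixin, BaseEstimator):
    """Random forest of vote-counting trees (sklearn estimator API).

    Parameters
    ----------
    n_trees : ensemble size (200 by default).
    n_split_candidates : features drawn without replacement at each split.
    criterion : only ``"information_gain"`` (entropy reduction).
    min_leaf : a node with fewer than ``2 * min_leaf`` samples becomes a leaf.
    max_depth : depth cap; ``None`` grows trees until pure.
    bootstrap : draw each tree's training set with replacement (size n).
    random_state : seed for bootstraps and feature subsampling.
    """

    def __init__(
        self,
        n_trees: int = 200,
        n_split_candidates: int = 16,
        criterion: str = "information_gain",
        min_leaf: int = 1,
        max_depth: int | None = None,
        bootstrap: bool = True,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.n_split_candidates = n_split_candidates
        self.criterion = criterion
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.bootstrap = bootstrap
        self.random_state = random_state

    def _grow(self, X, y, idx, depth, rng, n_classes, tree):
        feature, threshold, left, right, klass, counts = tree
        i = len(feature)
        for arr in tree:
            arr.append(0 if arr is counts else -1)
        counts[i] = np.bincount(y[idx], minlength=n_classes)
        threshold[i] = 0.0
        node_counts = counts[i]
        pure = np.count_nonzero(node_counts) <= 1
        too_small = idx.size < 2 * self.min_leaf
        too_deep = self.max_depth is not None and depth >= self.max_depth
        if not (pure or too_small or too_deep):
            k = min(self.n_split_candidates, X.shape[1])
            feats = rng.choice(X.shape[1], size=k, replace=False)
            f, t, gain = best_split(X, y, idx, feats, n_classes)
            if gain > _GAIN_TOL:
                feature[i], threshold[i] = f, t
                mask = X[idx, f] <= t
                left[i] = self._grow(X, y, idx[mask], depth + 1, rng, n_classes, tree)
                right[i] = self._grow(X, y, idx[~mask], depth + 1, rng, n_classes, tree)
                klass[i] = -1
                return i
        klass[i] = int(np.argmax(node_counts))  # ties -> lower class index
        feature[i] = -1
        return i

    def fit(self, X, y):
        if self.criterion != "information_gain":
            raise ValueError(f"unsupported criterion {self.criterion!r}")
        X, y = check_X_y(X, y, dtype=np.float64)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if self.n_split_candidates > X.shape[1]:
            raise ValueError(
                f"n_split_candidates={self.n_split_candidates} exceeds "
                f"{X.shape[1]} features"
            )
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self.n_features_in_ = X.shape[1]
        n_classes = len(self.classes_)
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_trees)
        self.trees_ = []
        n = X.shape[0]
        for ss in seeds:
            rng = np.random.default_rng(ss)
            idx = rng.integers(0, n, n) if self.bootstrap else np.arange(n)
            tree: tuple = ([], [], [], [], [], [])
            self._grow(X, y_enc, np.asarray(idx), 0, rng, n_classes, tree)
            self.trees_.append(_Tree(*tree))
        return self

    def _check_fitted(self, X):
        if not hasattr(self, "trees_"):
            raise NotFittedError("forest is not trained")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature vector has {X.shape[1]} entries, forest expects "
                f"{self.n_features_in_}"
            )
        return X

    def vote_counts(self, X) -> np.ndarray:
        """Per-class tree votes, shape (n_samples, n_classes)."""
        X = self._check_fitted(X)
        votes = np.zeros((X.shape[0], len(self.classes_)), dtype=np.int64)
        rows = np.arange(X.shape[0])
        for tree in self.trees_:
            votes[rows, tree.predict(X)] += 1
        return votes

    def predict_proba(self, X) -> np.ndarray:
        return self.vote_counts(X) / float(self.n_trees)

    def predict(self, X) -> np.ndarray:
        # argmax returns the first maximum: vote ties go to classes_[0]
        votes = self.vote_counts(X)
        return self.classes_[np.argmax(votes, axis=1)]

    def predict_one(self, fv: np.ndarray) -> Prediction:
        """Single-vector prediction with vote-fraction confidence."""
        votes = self.vote_counts(np.asarray(fv, dtype=float)[None, :])[0]
        k = int(np.argmax(votes))
        return Prediction(
            label=str(self.classes_[k]),
            confidence=float(votes[k]) / float(self.n_trees),
            votes={str(c): int(v) for c, v in zip(self.classes_, votes)},
        )


# ---------------------------------------------------------------------------
# spec-surface wrappers and JSON transfer


def train_forest(data, config: ForestConfig | None = None, schema_fingerprint: str | None = None):
    """Train a :class:`VoteForestClassifier` on a LabeledFrameSet."""
    cfg = config or ForestConfig()
    if len(data) == 0:
        raise ValueError("empty training set")
    clf = VoteForestClassifier(
        n_trees=cfg.n_trees,
        n_split_candidates=cfg.n_split_candidates,
        criterion=cfg.split_criterion,
        min_leaf=cfg.min_leaf,
        max_depth=cfg.max_depth,
        bootstrap=cfg.bootstrap,
        random_state=cfg.seed,
    )
    clf.fit(data.X, data.y)
    if schema_fingerprint is None and data.X.shape[1] == 260:
        from .features import feature_schema

        schema_fingerprint = feature_schema().fingerprint()
    clf.schema_fingerprint_ = schema_fingerprint
    return clf


def predict(forest: VoteForestClassifier, fv: np.ndarray) -> Prediction:
    """Majority-vote prediction for one feature vector."""
    return forest.predict_one(fv)


FORMAT_VERSION = 1


class ForestFormatError(ValueError):
    """Raised when serialized forest text is malformed."""


def serialize_forest(forest: VoteForestClassifier) -> str:
    """Serialize a trained forest to versioned JSON (full float precision)."""
    if not hasattr(forest, "trees_"):
        raise NotFittedError("cannot serialize an untrained forest")
    doc = {
        "format_version": FORMAT_VERSION,
        "config": {
            "n_trees": forest.n_trees,
            "n_split_candidates": forest.n_split_candidates,
            "criterion": forest.criterion,
            "min_leaf": forest.min_leaf,
            "max_depth": forest.max_depth,
            "bootstrap": forest.bootstrap,
            "random_state": forest.random_state,
        },
        "classes": [str(c) for c in forest.classes_],
        "n_features": int(forest.n_features_in_),
        "schema_fingerprint": getattr(forest, "schema_fingerprint_", None),
        "trees": [t.to_nested() for t in forest.trees_],
    }
    return json.dumps(doc)


def parse_forest(text: str) -> VoteForestClassifier:
    """Parse forest JSON back into a predictor (round-trip identical)."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ForestFormatError(
            f"malformed forest JSON at line {e.lineno}, column {e.colno}: {e.msg}"
        ) from e
    if not isinstance(doc, dict) or "format_version" not in doc:
        raise ForestFormatError("not a forest document: missing 'format_version'")
    if doc["format_version"] != FORMAT_VERSION:
        raise ForestFormatError(
            f"unsupported format_version {doc['format_version']!r} "
            f"(expected {FORMAT_VERSION})"
        )
    try:
        cfg = doc["config"]
        clf = VoteForestClassifier(
            n_trees=cfg["n_trees"],
            n_split_candidates=cfg["n_split_candidates"],
            criterion=cfg["criterion"],
            min_leaf=cfg["min_leaf"],
            max_depth=cfg["max_depth"],
            bootstrap=cfg.get("bootstrap", True),
            random_state=cfg["random_state"],
        )
        clf.classes_ = np.asarray(doc["classes"], dtype=object)
        clf.n_features_in_ = int(doc["n_features"])
        clf.schema_fingerprint_ = doc.get("schema_fingerprint")
        clf.trees_ = [
            _Tree.from_nested(t, len(clf.classes_)) for t in doc["trees"]
        ]
    except (KeyError, TypeError, ValueError) as e:
        raise ForestFormatError(f"invalid forest document field: {e}") from e
    if len(clf.trees_) != clf.n_trees:
        raise ForestFormatError(
            f"document declares {clf.n_trees} trees but contains {len(clf.trees_)}"
        )
    return clf
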