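"""A random forest built from first principles.

The ensemble grows ``n_trees`` (default 10) fully grown, unpruned
decision trees, each on a bootstrap replicate of the training set
(sampling N cases with replacement). At every node, m features are
drawn at random without replacement out of the M available — by default
m = floor(log2 M) + 1 — and the split maximizing impurity decrease
(information gain by default) over candidate thresholds at midpoints of
consecutive distinct sorted values is taken. Growth stops only when a
node is class-pure or none of the drawn candidate features separates
its samples — every leaf is pure or has no admissible split. Prediction
is the majority vote over trees; ties go to the first (negative) class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DecisionTree",
    "RandomForestDomainClassifier",
    "bootstrap_sample",
    "grow_tree",
    "fit_forest",
    "predict",
    "default_m",
    "forest_to_json",
    "forest_from_json",
]

FOREST_FORMAT_VERSION = 1


def default_m(n_features: int) -> int:
    """Features examined per node: floor(log2 M) + 1."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    return int(np.floor(np.log2(n_features))) + 1


def bootstrap_sample(n: int, rng) -> np.ndarray:
    """Indices of a bootstrap replicate: n draws with replacement from 0..n-1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    return rng.integers(0, n, size=n)


def _node_entropy(counts: np.ndarray) -> np.ndarray:
    """Entropy (nats) of rows of class-count vectors."""
    totals = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / totals, 0.0)
        logp = np.where(p > 0, np.log(p), 0.0)
    return -(p * logp).sum(axis=-1)


def _node_gini(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / totals, 0.0)
    return 1.0 - (p**2).sum(axis=-1)


_IMPURITY = {"entropy": _node_entropy, "gini": _node_gini}


@dataclass
class DecisionTree:
    """An unpruned binary decision tree stored as parallel arrays.

    ``feature[i] < 0`` marks a leaf; then ``leaf_class[i]`` is its class
    code. Internal nodes route ``x[feature] <= threshold`` to ``left``.
    ``bootstrap_indices`` and ``seed`` record how the tree was grown.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_class: np.ndarray
    bootstrap_indices: np.ndarray | None = None
    seed: int | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        """Class codes for each row of X (vectorized routing)."""
        X = np.asarray(X, dtype=float)
        node = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            feat = self.feature[node]
            internal = feat >= 0
            if not internal.any():
                return self.leaf_class[node]
            rows = np.nonzero(internal)[0]
            vals = X[rows, feat[rows]]
            go_left = vals <= self.threshold[node[rows]]
            node[rows] = np.where(
                go_left, self.left[node[rows]], self.right[node[rows]]
            )


def _best_split(X, y_codes, n_classes, candidates, impurity):
    """Best (gain, feature, threshold) over candidate features.

    Zero-gain splits are admissible (feature -1 is returned only when
    every candidate is constant): a fully grown tree keeps splitting
    impure nodes until purity or until no candidate separates the data,
    which is what lets consistent but non-linearly-separable labelings
    (XOR-like) be fit exactly.
    """
    best_gain = -np.inf
    best_feat = -1
    best_thr = 0.0
    n = y_codes.size
    onehot = np.eye(n_classes)[y_codes]
    parent_imp = impurity(onehot.sum(axis=0))
    for j in candidates:
        vals = X[:, j]
        order = np.argsort(vals, kind="stable")
        sv = vals[order]
        boundaries = np.nonzero(sv[:-1] < sv[1:])[0]
        if boundaries.size == 0:
            continue
        cum = np.cumsum(onehot[order], axis=0)
        left_counts = cum[boundaries]
        right_counts = cum[-1] - left_counts
        n_left = boundaries + 1
        n_right = n - n_left
        child_imp = (
            n_left * impurity(left_counts) + n_right * impurity(right_counts)
        ) / n
        gains = parent_imp - child_imp
        k = int(np.argmax(gains))
        if gains[k] > best_gain + 1e-12 or best_feat < 0:
            best_gain = float(gains[k])
            best_feat = int(j)
            best_thr = float((sv[boundaries[k]] + sv[boundaries[k] + 1]) / 2.0)
    return best_gain, best_feat, best_thr


def _grow(X, y_codes, n_classes, m, rng, criterion="entropy"):
    """Grow a fully grown, unpruned tree; returns parallel node arrays."""
    impurity = _IMPURITY[criterion]
    M = X.shape[1]
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    leaf_class: list[int] = []

    def majority(yc):
        counts = np.bincount(yc, minlength=n_classes)
        return int(np.argmax(counts))  # tie -> lowest class code

    # stack entries: (row indices, parent node id, is_left_child)
    stack: list[tuple[np.ndarray, int, bool]] = [(np.arange(X.shape[0]), -1, False)]
    while stack:
        idx, parent, is_left = stack.pop()
        node_id = len(feature)
        if parent >= 0:
            (left if is_left else right)[parent] = node_id
        yc = y_codes[idx]
        if np.all(yc == yc[0]):
            feature.append(-1)
            threshold.append(0.0)
            left.append(-1)
            right.append(-1)
            leaf_class.append(int(yc[0]))
            continue
        candidates = rng.choice(M, size=min(m, M), replace=False)
        gain, feat, thr = _best_split(X[idx], yc, n_classes, candidates, impurity)
        if feat < 0:
            feature.append(-1)
            threshold.append(0.0)
            left.append(-1)
            right.append(-1)
            leaf_class.append(majority(yc))
            continue
        feature.append(feat)
        threshold.append(thr)
        left.append(-1)
        right.append(-1)
        leaf_class.append(-1)
        mask = X[idx, feat] <= thr
        # push right first so the left child is grown (and numbered) next
        stack.append((idx[~mask], node_id, False))
        stack.append((idx[mask], node_id, True))
    return (
        np.asarray(feature, dtype=np.int64),
        np.asarray(threshold, dtype=float),
        np.asarray(left, dtype=np.int64),
        np.asarray(right, dtype=np.int64),
        np.asarray(leaf_class, dtype=np.int64),
    )


class RandomForestDomainClassifier:
    """Random forest classifier (scikit-learn estimator conventions).

    Parameters
    ----------
    n_trees : int, default 10
        Ensemble size.
    m_features : int or None
        Features drawn per node; None means floor(log2 M) + 1.
    bootstrap : bool, default True
        Grow each tree on an N-sample bootstrap replicate; disabling it
        (a test hook) grows every tree on the full training set.
    criterion : {"entropy", "gini"}, default "entropy"
        Split impurity measure; information gain (entropy) is the default.
    random_state : int or None
        Master seed; per-tree seeds are spawned from it.

    Attributes (after fit)
    ----------------------
    classes_ : sorted unique labels; a vote tie resolves to classes_[0],
        which for {0,1} or {"negative","positive"} labels is the
        negative class.
    trees_ : list of DecisionTree.
    m_, n_features_in_ : resolved per-node feature count and M.
    """

    def __init__(
        self,
        n_trees: int = 10,
        m_features: int | None = None,
        bootstrap: bool = True,
        criterion: str = "entropy",
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.m_features = m_features
        self.bootstrap = bootstrap
        self.criterion = criterion
        self.random_state = random_state

    _param_names = ("n_trees", "m_features", "bootstrap", "criterion", "random_state")

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params) -> "RandomForestDomainClassifier":
        for key, value in params.items():
            if key not in self._param_names:
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "RandomForestDomainClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if X.shape[0] < 1:
            raise ValueError("need at least one sample")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.criterion not in _IMPURITY:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        n, M = X.shape
        self.n_features_in_ = M
        self.m_ = self.m_features if self.m_features is not None else default_m(M)
        if not 1 <= self.m_ <= M:
            raise ValueError(f"m_features must be in [1, {M}]")
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_trees)
        self.trees_ = []
        for t in range(self.n_trees):
            rng = np.random.default_rng(seeds[t])
            if self.bootstrap:
                idx = bootstrap_sample(n, rng)
            else:
                idx = np.arange(n)
            arrays = _grow(
                X[idx], y_codes[idx], len(self.classes_), self.m_, rng, self.criterion
            )
            self.trees_.append(
                DecisionTree(*arrays, bootstrap_indices=idx, seed=t)
            )
        return self

    def vote_counts(self, X) -> np.ndarray:
        """Per-sample vote tally of shape (n, n_classes)."""
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], len(self.classes_)), dtype=np.int64)
        for tree in self.trees_:
            codes = tree.predict_codes(X)
            votes[np.arange(X.shape[0]), codes] += 1
        return votes

    def predict(self, X) -> np.ndarray:
        """Majority-vote class per sample; ties resolve to classes_[0]."""
        votes = self.vote_counts(X)
        return self.classes_[np.argmax(votes, axis=1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


# ---------------------------------------------------------------------------
# thin functional wrappers

def grow_tree(X, y, m: int | None = None, seed: int | None = None,
              criterion: str = "entropy") -> DecisionTree:
    """Grow one unpruned tree on the full data (no bootstrap)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_codes = np.unique(y, return_inverse=True)
    m = m if m is not None else default_m(X.shape[1])
    rng = np.random.default_rng(seed)
    arrays = _grow(X, y_codes, len(classes), m, rng, criterion)
    tree = DecisionTree(*arrays, bootstrap_indices=None, seed=seed)
    tree.classes_ = classes  # type: ignore[attr-defined]
    return tree


def fit_forest(X, y, n_trees: int = 10, seed: int | None = None,
               m: int | None = None, bootstrap: bool = True) -> RandomForestDomainClassifier:
    return RandomForestDomainClassifier(
        n_trees=n_trees, m_features=m, bootstrap=bootstrap, random_state=seed
    ).fit(X, y)


def predict(forest: RandomForestDomainClassifier, X) -> np.ndarray:
    return forest.predict(np.atleast_2d(X))


# ---------------------------------------------------------------------------
# serialization

def forest_to_json(forest: RandomForestDomainClassifier, path,
                   feature_names: list[str] | None = None) -> None:
    """Serialize a fitted forest to a versioned JSON file."""
    payload = {
        "format_version": FOREST_FORMAT_VERSION,
        "params": forest.get_params(),
        "classes": [c.item() if hasattr(c, "item") else c for c in forest.classes_],
        "feature_names": feature_names,
        "trees": [
            {
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "left": t.left.tolist(),
                "right": t.right.tolist(),
                "leaf_class": t.leaf_class.tolist(),
                "seed": t.seed,
            }
            for t in forest.trees_
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def forest_from_json(path) -> tuple[RandomForestDomainClassifier, list[str] | None]:
    """Load a forest serialized by :func:`forest_to_json`."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format_version") != FOREST_FORMAT_VERSION:
        raise ValueError(f"unsupported forest format: {payload.get('format_version')}")
    forest = RandomForestDomainClassifier(**payload["params"])
    forest.classes_ = np.asarray(payload["classes"])
    forest.trees_ = [
        DecisionTree(
            feature=np.asarray(t["feature"], dtype=np.int64),
            threshold=np.asarray(t["threshold"], dtype=float),
            left=np.asarray(t["left"], dtype=np.int64),
            right=np.asarray(t["right"], dtype=np.int64),
            leaf_class=np.asarray(t["leaf_class"], dtype=np.int64),
            seed=t.get("seed"),
        )
        for t in payload["trees"]
    ]
    if forest.trees_:
        internal = forest.trees_[0].feature
        forest.n_features_in_ = int(internal.max() + 1) if (internal >= 0).any() else 0
    return forest, payload.get("feature_names")
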