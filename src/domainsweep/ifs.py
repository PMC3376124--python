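"""Incremental feature selection over an mRMR-ranked feature list.

Nested feature prefixes S_i (the first i*l ranked features) are each
evaluated by 5-fold cross-validation of the random forest; the curve of
Matthews correlation coefficients locates the optimal prefix, and a
final winnowing pass keeps only the 5-feature blocks whose addition
improved the MCC over the previous prefix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .encoding import parse_feature_name, pssm_feature_amino_acid
from .forest import RandomForestDomainClassifier

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """Pooled binary confusion counts (positive = domain residue)."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )

    @staticmethod
    def from_predictions(y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        if y_true.shape != y_pred.shape:
            raise ValueError("shape mismatch")
        return ConfusionCounts(
            tp=int(np.sum(y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
        )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """Sensitivity, specificity, accuracy and MCC from confusion counts.

    Sn = TP/(TP+FN); Sp = TN/(TN+FP); Ac = (TP+TN)/total;
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    A zero factor under the square root makes the MCC 0 by convention.
    Sn (resp. Sp) is 0 when no positives (negatives) were evaluated.
    """
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    ac = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return sn, sp, ac, mcc


def five_fold_partition(n: int, seed, groups=None) -> list[np.ndarray]:
    """Random 5-way partition of range(n) with fold sizes differing by <= 1.

    With ``groups`` (e.g. protein ids) all samples of a group land in
    one fold (greedy balancing), so folds are protein-disjoint.
    """
    if n < 5:
        raise ValueError("need at least 5 samples for 5-fold cross-validation")
    rng = np.random.default_rng(seed)
    if groups is None:
        perm = rng.permutation(n)
        return [perm[k::5] for k in range(5)]
    groups = np.asarray(groups)
    uniq = rng.permutation(np.unique(groups))
    folds: list[list[int]] = [[] for _ in range(5)]
    sizes = np.zeros(5, dtype=int)
    for g in uniq:
        members = np.nonzero(groups == g)[0]
        k = int(np.argmin(sizes))
        folds[k].extend(members.tolist())
        sizes[k] += members.size
    return [np.asarray(f, dtype=int) for f in folds]


def five_fold_cv(
    X,
    y,
    feature_subset=None,
    seed=None,
    n_trees: int = 10,
    groups=None,
    forest_params: dict | None = None,
) -> ConfusionCounts:
    """5-fold cross-validated confusion counts for a forest on a feature subset.

    The data are randomly partitioned into 5 folds of near-equal size;
    each fold is predicted once by a forest trained on the other four,
    and the counts are pooled. A training fold collapsing to one class
    is logged but still evaluated (the forest then predicts constantly).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if feature_subset is not None:
        X = X[:, np.asarray(feature_subset, dtype=int)]
    folds = five_fold_partition(X.shape[0], seed, groups=groups)
    rng = np.random.default_rng(seed)
    pooled = ConfusionCounts()
    for k, test_idx in enumerate(folds):
        train_idx = np.concatenate([folds[j] for j in range(5) if j != k])
        y_train = y[train_idx]
        if np.unique(y_train).size < 2:
            logger.warning("fold %d: training data has a single class", k)
        params = dict(n_trees=n_trees, random_state=int(rng.integers(2**31)))
        if forest_params:
            params.update(forest_params)
        clf = RandomForestDomainClassifier(**params).fit(X[train_idx], y_train)
        pooled = pooled + ConfusionCounts.from_predictions(
            y[test_idx], clf.predict(X[test_idx])
        )
    return pooled


@dataclass
class IFSRow:
    """One point of the IFS curve: metrics of the i-th feature prefix."""

    subset_index: int  # i, starting at 1
    n_features: int  # i * l
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float


def ifs_curve(
    X,
    y,
    ranking,
    l: int = 5,
    seed=None,
    n_trees: int = 10,
    groups=None,
    forest_params: dict | None = None,
) -> list[IFSRow]:
    """Evaluate nested mRMR prefixes S_i = first i*l features, i=1..floor(N/l).

    Each prefix gets one 5-fold cross-validation of the forest; the
    trailing N mod l features are never evaluated. All prefixes share
    the same CV partition seed so rows are comparable.
    """
    if l < 1:
        raise ValueError("step l must be >= 1")
    ranking = np.asarray(ranking, dtype=int)
    n_subsets = len(ranking) // l
    rows: list[IFSRow] = []
    for i in range(1, n_subsets + 1):
        counts = five_fold_cv(
            X, y, ranking[: i * l], seed=seed, n_trees=n_trees,
            groups=groups, forest_params=forest_params,
        )
        sn, sp, ac, mcc = metrics(counts)
        rows.append(IFSRow(i, i * l, sn, sp, ac, mcc))
    return rows


def optimal_set(curve: list[IFSRow], ranking) -> np.ndarray:
    """The feature prefix with maximal MCC; ties go to the smaller prefix."""
    if not curve:
        raise ValueError("empty IFS curve")
    best = max(curve, key=lambda r: (r.mcc, -r.subset_index))
    return np.asarray(ranking, dtype=int)[: best.n_features]


def winnow_final(curve: list[IFSRow], ranking, gap: int = 5) -> np.ndarray:
    """Final MCC-based winnowing of the ranked list into the optimal feature set.

    Walking the IFS curve in steps of ``gap`` features, each block of
    ``gap`` newly added features is kept iff its prefix's MCC strictly
    exceeds the previous prefix's MCC. The first block has no
    predecessor and is always kept as the baseline.
    """
    if not curve:
        raise ValueError("empty IFS curve")
    ranking = np.asarray(ranking, dtype=int)
    kept = list(range(min(gap, len(ranking))))  # block 1, always
    for i in range(1, len(curve)):
        if curve[i].mcc > curve[i - 1].mcc:
            kept.extend(range(i * gap, min((i + 1) * gap, len(ranking))))
    return ranking[kept]


@dataclass
class FeatureSummary:
    """Composition of a selected feature set, parsed from feature names."""

    by_type: dict[str, int] = field(default_factory=dict)
    by_subsite: dict[int, int] = field(default_factory=dict)
    pssm_by_amino_acid: dict[str, int] = field(default_factory=dict)
    n_features: int = 0


_TYPE_ALIASES = {"pssm": "pssm", "disorder": "disorder", "aaf": "aafactor",
                 "ss": "ss", "sa": "sa"}


def summarize_features(feature_names, w: int) -> FeatureSummary:
    """Count selected features by type, by subsite, and PSSM ones by amino acid."""
    summary = FeatureSummary(
        by_type={t: 0 for t in ("pssm", "disorder", "aafactor", "ss", "sa")},
        by_subsite={s: 0 for s in range(1, w + 1)},
        pssm_by_amino_acid={},
        n_features=0,
    )
    for name in feature_names:
        subsite, ftype, idx = parse_feature_name(name)
        if subsite not in summary.by_subsite:
            raise ValueError(f"feature {name!r}: subsite {subsite} outside 1..{w}")
        summary.by_type[_TYPE_ALIASES[ftype]] += 1
        summary.by_subsite[subsite] += 1
        if ftype == "pssm":
            aa = pssm_feature_amino_acid(idx)
            summary.pssm_by_amino_acid[aa] = summary.pssm_by_amino_acid.get(aa, 0) + 1
        summary.n_features += 1
    return summary
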