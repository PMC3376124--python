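"""Maximum-relevance / minimum-redundancy feature ranking.

Features are scored by mutual information (MI, natural log) with the
class after discretizing each continuous feature into three states at
mean +/- k*sigma. Relevance D of a feature is its MI with the class;
redundancy R is its mean MI with the already-selected features. The
greedy mRMR loop picks, each round, the remaining feature maximizing
D - R; the MaxRel list simply sorts features by D. Earlier selection
round means a better relevance/redundancy trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscreteVariable:
    """A discretized variable: integer state codes per sample."""

    states: np.ndarray  # int codes 0..arity-1, one per sample
    arity: int

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.arity < 1:
            raise ValueError("arity must be >= 1")
        if self.states.size and (self.states.min() < 0 or self.states.max() >= self.arity):
            raise ValueError("state codes outside [0, arity)")


def discretize(values, k_sigma: float = 1.0) -> DiscreteVariable:
    """Discretize a continuous feature into at most 3 states.

    Thresholds are mean - k*sigma and mean + k*sigma (boundaries
    inclusive toward the outer states, so an exact 0/1 indicator keeps
    its two states at k_sigma=1). Constant input yields arity 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 samples to discretize")
    mu = values.mean()
    sigma = values.std()
    if sigma == 0.0:
        return DiscreteVariable(np.zeros(values.size, dtype=np.int64), 1)
    raw = np.ones(values.size, dtype=np.int64)
    raw[values <= mu - k_sigma * sigma] = 0
    raw[values >= mu + k_sigma * sigma] = 2
    present, states = np.unique(raw, return_inverse=True)
    return DiscreteVariable(states, len(present))


def encode_labels(y) -> DiscreteVariable:
    """Encode a class vector as a DiscreteVariable."""
    present, states = np.unique(np.asarray(y), return_inverse=True)
    return DiscreteVariable(states, len(present))


def mutual_information(x: DiscreteVariable, y: DiscreteVariable) -> float:
    """Plug-in mutual information estimate, in nats.

    I(X;Y) = sum_xy p(x,y) log( p(x,y) / (p(x) p(y)) ), over the
    empirical joint distribution. Symmetric and non-negative.
    """
    if x.states.size != y.states.size:
        raise ValueError("variables must have equal sample counts")
    n = x.states.size
    if n == 0:
        raise ValueError("cannot estimate MI from zero samples")
    joint = np.bincount(
        x.states * y.arity + y.states, minlength=x.arity * y.arity
    ).reshape(x.arity, y.arity)
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def entropy(x: DiscreteVariable) -> float:
    """Shannon entropy in nats (equals MI(x, x))."""
    p = np.bincount(x.states, minlength=x.arity) / x.states.size
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def relevance(feature: DiscreteVariable, target: DiscreteVariable) -> float:
    """Relevance D of a feature: its MI with the class."""
    return mutual_information(feature, target)


def redundancy(feature: DiscreteVariable, selected: list[DiscreteVariable]) -> float:
    """Redundancy R: mean MI between a feature and the selected set (0 if empty)."""
    if not selected:
        return 0.0
    return float(np.mean([mutual_information(feature, g) for g in selected]))


@dataclass
class RankedFeatures:
    """MaxRel and mRMR orderings over a feature set.

    maxrel : list of (feature_name, D) sorted by descending relevance.
    mrmr : list of (feature_name, selection_round, D - R at selection);
        rounds start at 1; earlier round = better feature.
    """

    maxrel: list[tuple[str, float]]
    mrmr: list[tuple[str, int, float]]
    feature_names: list[str]

    @property
    def mrmr_order(self) -> list[str]:
        return [name for name, _, _ in self.mrmr]

    @property
    def mrmr_indices(self) -> list[int]:
        pos = {name: i for i, name in enumerate(self.feature_names)}
        return [pos[name] for name in self.mrmr_order]


class MRMRRanker:
    """Greedy mRMR feature ranker (scikit-learn estimator conventions).

    Parameters
    ----------
    k_sigma : float, default 1.0
        Width of the 3-state discretization band, mean +/- k_sigma * std.
    n_select : int or None
        Number of greedy rounds; None ranks every feature.

    Attributes (after fit)
    ----------------------
    relevance_ : (M,) array of D values per feature.
    ranking_ : (R,) array of feature indices in mRMR selection order.
    scores_ : (R,) array of D - R at each selection round.
    maxrel_order_ : (M,) array of feature indices sorted by descending D
        (ties broken by lower index).
    n_features_in_ : int.
    """

    def __init__(self, k_sigma: float = 1.0, n_select: int | None = None):
        self.k_sigma = k_sigma
        self.n_select = n_select

    def get_params(self, deep: bool = True) -> dict:
        return {"k_sigma": self.k_sigma, "n_select": self.n_select}

    def set_params(self, **params) -> "MRMRRanker":
        for key, value in params.items():
            if key not in ("k_sigma", "n_select"):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "MRMRRanker":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        n, M = X.shape
        if M < 1:
            raise ValueError("need at least one feature")
        self.n_features_in_ = M
        target = encode_labels(y)
        feats = [discretize(X[:, j], self.k_sigma) for j in range(M)]
        D = np.array([mutual_information(f, target) for f in feats])
        self.relevance_ = D
        # stable sort => ties broken by lower feature index
        self.maxrel_order_ = np.argsort(-D, kind="stable")

        n_rounds = M if self.n_select is None else min(self.n_select, M)
        remaining = np.ones(M, dtype=bool)
        mi_sum = np.zeros(M)  # cumulative MI of each candidate vs selected set
        ranking: list[int] = []
        scores: list[float] = []
        for round_no in range(n_rounds):
            if round_no == 0:
                crit = D.copy()
            else:
                crit = D - mi_sum / round_no
            crit[~remaining] = -np.inf
            pick = int(np.argmax(crit))  # argmax takes the lowest index on ties
            ranking.append(pick)
            scores.append(float(crit[pick]))
            remaining[pick] = False
            if round_no + 1 < n_rounds:
                picked = feats[pick]
                for j in np.nonzero(remaining)[0]:
                    mi_sum[j] += mutual_information(feats[j], picked)
        self.ranking_ = np.array(ranking, dtype=int)
        self.scores_ = np.array(scores)
        return self

    def ranked_features(self, feature_names: list[str]) -> RankedFeatures:
        """Package fitted rankings with names into a RankedFeatures record."""
        if len(feature_names) != self.n_features_in_:
            raise ValueError("feature_names length mismatch")
        maxrel = [(feature_names[j], float(self.relevance_[j])) for j in self.maxrel_order_]
        mrmr = [
            (feature_names[j], r + 1, float(self.scores_[r]))
            for r, j in enumerate(self.ranking_)
        ]
        return RankedFeatures(maxrel=maxrel, mrmr=mrmr, feature_names=list(feature_names))


def mrmr_rank(samples, k_sigma: float = 1.0, n_select: int | None = None) -> RankedFeatures:
    """Rank a SampleSet's features by MaxRel and by mRMR."""
    ranker = MRMRRanker(k_sigma=k_sigma, n_select=n_select).fit(samples.X, samples.y)
    return ranker.ranked_features(samples.feature_names)
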