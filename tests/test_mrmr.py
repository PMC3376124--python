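"""Mutual information, discretization and the greedy mRMR ranking."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import mutual_info_score

from domainsweep.mrmr import (
    DiscreteVariable,
    MRMRRanker,
    discretize,
    encode_labels,
    entropy,
    mrmr_rank,
    mutual_information,
    redundancy,
    relevance,
)


def _dv(codes):
    codes = np.asarray(codes)
    return DiscreteVariable(codes, int(codes.max()) + 1 if codes.size else 1)


# --- discretization ----------------------------------------------------------

def test_discretize_constant_input():
    assert discretize(np.full(10, 3.3)).arity == 1


def test_discretize_three_state_split_fractions():
    rng = np.random.default_rng(0)
    x = rng.normal(size=10000)
    d = discretize(x, k_sigma=1.0)
    assert d.arity == 3
    frac = np.bincount(d.states) / x.size
    # Normal tails: ~16 / 68 / 16 percent
    assert abs(frac[0] - 0.16) < 0.02
    assert abs(frac[1] - 0.68) < 0.02
    assert abs(frac[2] - 0.16) < 0.02


def test_discretize_preserves_binary_indicator():
    x = np.array([0.0, 1.0, 0.0, 0.0, 1.0, 1.0])
    assert discretize(x, k_sigma=1.0).arity == 2
    skew = np.array([0.0] * 9 + [1.0])
    assert discretize(skew, k_sigma=1.0).arity == 2


# --- mutual information ------------------------------------------------------

def mi_bruteforce(joint: np.ndarray) -> float:
    """Direct summation over a joint count table (independent oracle)."""
    n = joint.sum()
    px = joint.sum(axis=1) / n
    py = joint.sum(axis=0) / n
    mi = 0.0
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            p = joint[i, j] / n
            if p > 0:
                mi += p * math.log(p / (px[i] * py[j]))
    return mi


def expand_table(joint: np.ndarray):
    xs, ys = [], []
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            xs += [i] * joint[i, j]
            ys += [j] * joint[i, j]
    return (
        DiscreteVariable(np.array(xs), joint.shape[0]),
        DiscreteVariable(np.array(ys), joint.shape[1]),
    )


def test_mi_against_bruteforce_and_sklearn():
    joint = np.array([[2, 1], [1, 2]])
    x, y = expand_table(joint)
    got = mutual_information(x, y)
    assert got == pytest.approx(mi_bruteforce(joint), abs=1e-12)
    assert got == pytest.approx(mutual_info_score(x.states, y.states), abs=1e-12)


def test_mi_independence_limit():
    rng = np.random.default_rng(1)
    x = _dv(rng.integers(0, 3, 50000))
    y = _dv(rng.integers(0, 2, 50000))
    assert mutual_information(x, y) < 5e-4


def test_mi_of_identical_uniform_binary_is_log2():
    x = _dv(np.tile([0, 1], 500))
    assert mutual_information(x, x) == pytest.approx(math.log(2), abs=1e-12)


@given(
    st.lists(st.integers(0, 2), min_size=2, max_size=40),
    st.lists(st.integers(0, 3), min_size=2, max_size=40),
)
def test_mi_symmetry_nonnegativity_self_entropy(xs, ys):
    n = min(len(xs), len(ys))
    x, y = _dv(np.array(xs[:n])), _dv(np.array(ys[:n]))
    mxy = mutual_information(x, y)
    assert mxy >= -1e-15
    assert mxy == pytest.approx(mutual_information(y, x), abs=1e-12)
    assert mutual_information(x, x) == pytest.approx(entropy(x), abs=1e-12)


# --- relevance / redundancy --------------------------------------------------

def test_relevance_of_label_itself_is_label_entropy():
    y = np.array([0, 1, 1, 0, 1, 1])
    target = encode_labels(y)
    assert relevance(target, target) == pytest.approx(entropy(target), abs=1e-12)


def test_relevance_of_noise_is_near_zero():
    rng = np.random.default_rng(2)
    y = encode_labels(rng.integers(0, 2, 20000))
    f = _dv(rng.integers(0, 3, 20000))
    assert relevance(f, y) < 5e-4


def test_redundancy_cases():
    f = _dv(np.array([0, 1, 0, 1, 1, 0]))
    g = _dv(np.array([0, 0, 1, 1, 0, 1]))
    assert redundancy(f, []) == 0.0
    assert redundancy(f, [f]) == pytest.approx(entropy(f), abs=1e-12)
    expected = (mutual_information(f, f) + mutual_information(f, g)) / 2
    assert redundancy(f, [f, g]) == pytest.approx(expected, abs=1e-12)


# --- greedy ranking ----------------------------------------------------------

def greedy_oracle(X, y, k_sigma=1.0):
    """Exhaustive greedy recomputation of the mRMR ordering (no caching)."""
    target = encode_labels(y)
    feats = [discretize(X[:, j], k_sigma) for j in range(X.shape[1])]
    D = [mutual_information(f, target) for f in feats]
    selected: list[int] = []
    remaining = list(range(X.shape[1]))
    while remaining:
        best_j, best_score = None, None
        for j in remaining:  # ascending index: ties keep the lower index
            score = D[j] - redundancy(feats[j], [feats[g] for g in selected])
            if best_score is None or score > best_score:
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
    return selected


def test_mrmr_matches_bruteforce_greedy_oracle():
    rng = np.random.default_rng(3)
    for trial in range(30):
        n = int(rng.integers(20, 80))
        m = int(rng.integers(2, 9))
        X = rng.normal(size=(n, m))
        if trial % 3 == 0 and m >= 2:
            X[:, 1] = X[:, 0]  # exact duplicate exercises tie handling
        y = rng.integers(0, 2, n)
        ranker = MRMRRanker().fit(X, y)
        assert ranker.ranking_.tolist() == greedy_oracle(X, y)


def test_mrmr_first_pick_is_maxrel_top():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(100, 6))
    y = (X[:, 2] > 0).astype(int)
    ranker = MRMRRanker().fit(X, y)
    assert ranker.ranking_[0] == ranker.maxrel_order_[0] == 2


def test_two_feature_ordering_by_relevance():
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 400)
    informative = y + rng.normal(0, 0.1, 400)
    noise = rng.normal(size=400)
    ranker = MRMRRanker().fit(np.column_stack([noise, informative]), y)
    assert ranker.ranking_.tolist() == [1, 0]


def test_duplicate_of_selected_feature_is_deprioritized():
    """After selecting a strong feature, its exact copy ranks below an
    independent weaker feature (minimum-redundancy behavior)."""
    rng = np.random.default_rng(6)
    n = 2000
    y = rng.integers(0, 2, n)
    strong = y + rng.normal(0, 0.3, n)
    weak = y + rng.normal(0, 2.0, n)
    X = np.column_stack([strong, strong.copy(), weak])
    ranker = MRMRRanker().fit(X, y)
    d_weak = ranker.relevance_[2]
    assert d_weak > 0.005  # the weak feature genuinely carries signal
    assert ranker.ranking_.tolist() == [0, 2, 1]


def test_log_base_does_not_change_ordering():
    """Scaling MI by a constant (log base change) rescales D and R jointly,
    leaving the greedy ordering unchanged."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(150, 6))
    y = (X[:, 0] + X[:, 3] > 0).astype(int)
    nats = MRMRRanker().fit(X, y)

    def greedy_base2(X, y):
        target = encode_labels(y)
        feats = [discretize(X[:, j]) for j in range(X.shape[1])]
        D = [mutual_information(f, target) / math.log(2) for f in feats]
        selected, remaining = [], list(range(X.shape[1]))
        while remaining:
            best_j, best = None, None
            for j in remaining:
                r = (
                    np.mean([mutual_information(feats[j], feats[g]) for g in selected])
                    / math.log(2)
                    if selected
                    else 0.0
                )
                score = D[j] - r
                if best is None or score > best:
                    best_j, best = j, score
            selected.append(best_j)
            remaining.remove(best_j)
        return selected

    assert nats.ranking_.tolist() == greedy_base2(X, y)


def test_planted_feature_outranks_noise(planted_run):
    """Every planted channel's relevance exceeds every no-effect channel's."""
    samples = planted_run["samples"]
    ranker = planted_run["ranker"]
    names = samples.feature_names
    planted_idx = {names.index(n) for n in planted_run["planted"]}
    planted_channels = {n.split("_", 1)[1] for n in planted_run["planted"]}
    # pure-noise features: conservation channels with zero planted effect,
    # at any subsite (categorical channels carry signal in this condition)
    noise_idx = [
        j for j, n in enumerate(names)
        if "_pssm_" in n and n.split("_", 1)[1] not in planted_channels
    ]
    d = ranker.relevance_
    assert min(d[j] for j in planted_idx) > max(d[j] for j in noise_idx)


def test_mrmr_rank_wrapper_returns_named_lists(planted_run):
    ranked = mrmr_rank(planted_run["samples"], n_select=5)
    assert len(ranked.mrmr) == 5
    assert ranked.mrmr[0][0] == ranked.maxrel[0][0]
    assert ranked.mrmr[0][1] == 1
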