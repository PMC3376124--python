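"""Shared fixtures: the standard synthetic study conditions.

The expensive stochastic runs (planted-signal recovery, null control,
moderate-signal IFS/winnowing) are computed once per session and shared
by the module tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from domainsweep.ifs import five_fold_cv, ifs_curve, metrics, winnow_final
from domainsweep.mrmr import MRMRRanker
from domainsweep.pipeline import encode_proteins
from domainsweep.synthetic import generate, null_config, planted_config

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_run():
    """Strong planted signal: 10 informative channels at 3 std, ~2000 residues.

    Returns the generated data, encoded windows, the mRMR top-20
    ranking, the recall of the planted center-subsite features in the
    top 20, and the 5-fold CV metrics on the top-20 feature subset.
    """
    cfg = planted_config(
        n_informative=10, effect=3.0, seed=42,
        n_proteins=8, length_min=200, length_max=300,
    )
    data = generate(cfg)
    samples = encode_proteins(data.records, data.blocks, 13)
    ranker = MRMRRanker(n_select=20).fit(samples.X, samples.y)
    ranked = ranker.ranked_features(samples.feature_names)
    planted = set(cfg.planted_feature_names(13))
    top20 = {name for name, _, _ in ranked.mrmr}
    recall = len(planted & top20) / len(planted)
    counts = five_fold_cv(samples.X, samples.y, ranker.ranking_, seed=7)
    return {
        "config": cfg,
        "data": data,
        "samples": samples,
        "ranker": ranker,
        "ranked": ranked,
        "planted": planted,
        "recall_top20": recall,
        "cv_counts": counts,
        "cv_metrics": metrics(counts),
    }


@pytest.fixture(scope="session")
def null_run():
    """Null control: no feature carries class signal, ~5000 residues."""
    cfg = null_config(seed=11, n_proteins=20, length_min=200, length_max=300)
    data = generate(cfg)
    samples = encode_proteins(data.records, data.blocks, 13)
    ranker = MRMRRanker(n_select=20).fit(samples.X, samples.y)
    counts = five_fold_cv(samples.X, samples.y, ranker.ranking_, seed=7)
    return {
        "config": cfg,
        "samples": samples,
        "cv_metrics": metrics(counts),
    }


@pytest.fixture(scope="session")
def moderate_run():
    """Moderate planted signal (1 std): the IFS curve keeps growing past the
    first block, exercising winnowing under realistic (non-saturated) MCC."""
    cfg = planted_config(
        n_informative=10, effect=1.0, seed=42,
        n_proteins=8, length_min=200, length_max=300,
    )
    data = generate(cfg)
    samples = encode_proteins(data.records, data.blocks, 13)
    ranker = MRMRRanker(n_select=40).fit(samples.X, samples.y)
    curve = ifs_curve(samples.X, samples.y, ranker.ranking_, l=5, seed=7)
    final_idx = winnow_final(curve, ranker.ranking_, gap=5)
    final_names = {samples.feature_names[j] for j in final_idx}
    planted = set(cfg.planted_feature_names(13))
    return {
        "config": cfg,
        "samples": samples,
        "ranker": ranker,
        "curve": curve,
        "final_idx": final_idx,
        "final_names": final_names,
        "planted": planted,
        "winnow_recall": len(planted & final_names) / len(planted),
    }
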