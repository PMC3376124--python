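"""Window encoding: Atchley factors, labeling, padding, layout, dedup."""

import numpy as np
import pytest

from domainsweep.encoding import (
    ATCHLEY_FACTORS,
    BLOCK_SIZE,
    assemble_blocks,
    atchley_factors,
    dedupe_samples,
    feature_names,
    label_residues,
    make_windows,
    parse_feature_name,
)
from domainsweep.io import AMINO_ACIDS, ProteinRecord


def _record(seq="ACDEFGHIKLMNPQRSTVWY", domains=()):
    return ProteinRecord("p1", seq, list(domains))


def _blocks(record, rng=None):
    L = len(record.sequence)
    rng = rng or np.random.default_rng(0)
    ss = np.zeros((L, 3))
    ss[np.arange(L), rng.integers(0, 3, L)] = 1
    sa = np.zeros((L, 2))
    sa[np.arange(L), rng.integers(0, 2, L)] = 1
    return assemble_blocks(
        record.sequence,
        rng.normal(size=(L, 20)),
        rng.random(L),
        ss,
        sa,
    )


# --- Atchley factors ---------------------------------------------------------

def test_atchley_table_shape_and_standardization():
    assert set(ATCHLEY_FACTORS) == set(AMINO_ACIDS)
    table = np.array([ATCHLEY_FACTORS[aa] for aa in AMINO_ACIDS])
    assert table.shape == (20, 5)
    # the factors are standardized scores: each column mean is near zero
    assert np.all(np.abs(table.mean(axis=0)) < 0.2)


def test_atchley_x_is_zero_and_unknown_errors():
    assert atchley_factors("X") == (0.0,) * 5
    assert atchley_factors("A") == ATCHLEY_FACTORS["A"]
    with pytest.raises(ValueError):
        atchley_factors("B")


# --- labeling ----------------------------------------------------------------

@pytest.mark.parametrize(
    "domains,expected",
    [
        ([(2, 3)], [False, True, True, False]),
        ([], [False] * 4),
        ([(1, 4)], [True] * 4),
    ],
)
def test_label_residues(domains, expected):
    rec = ProteinRecord("p", "ACDE", domains)
    assert label_residues(rec).tolist() == expected


# --- windows -----------------------------------------------------------------

@pytest.mark.parametrize("w,dim", [(13, 403), (15, 465), (17, 527)])
def test_window_vector_dimensionality(w, dim):
    rec = _record()
    samples = make_windows(rec, _blocks(rec), w)
    assert samples.X.shape == (len(rec.sequence), dim)
    assert len(samples.feature_names) == dim


def test_single_residue_protein_pads_all_flanks():
    rec = ProteinRecord("p1", "A", [(1, 1)])
    samples = make_windows(rec, _blocks(rec), 13)
    assert len(samples) == 1
    vec = samples.X[0].reshape(13, BLOCK_SIZE)
    # only the center subsite (7th of 13) may be non-zero
    assert np.all(vec[:6] == 0) and np.all(vec[7:] == 0)
    assert np.any(vec[6] != 0)
    assert samples.window_seqs[0] == "X" * 6 + "A" + "X" * 6
    assert samples.y[0] == 1


def test_one_sample_per_residue_and_label_partition():
    rec = _record(domains=[(3, 10)])
    samples = make_windows(rec, _blocks(rec), 13)
    assert len(samples) == len(rec.sequence)
    assert samples.y.sum() == 8
    assert (samples.y == 0).sum() + (samples.y == 1).sum() == len(rec.sequence)


def test_even_window_rejected():
    rec = _record()
    with pytest.raises(ValueError, match="odd"):
        make_windows(rec, _blocks(rec), 12)


def test_subsite_major_layout_zeroing_is_contiguous():
    """Zeroing residue i's block zeroes exactly one contiguous 31-slice of
    every window containing i, at the slice matching i's subsite."""
    rec = _record()
    blocks = _blocks(rec)
    w = 13
    base = make_windows(rec, blocks, w)
    i = 9  # 0-based residue to zero
    blocks2 = blocks.copy()
    blocks2[i] = 0.0
    changed = make_windows(rec, blocks2, w)
    diff = base.X != changed.X
    half = w // 2
    for s in range(len(base)):
        subsite = i - (s - half)  # 0-based subsite of residue i in window s
        cols = np.nonzero(diff[s])[0]
        if 0 <= subsite < w and np.any(cols >= 0):
            assert cols.size <= BLOCK_SIZE
            lo, hi = subsite * BLOCK_SIZE, (subsite + 1) * BLOCK_SIZE
            assert np.all((cols >= lo) & (cols < hi))
        else:
            assert cols.size == 0


def test_feature_names_follow_subsite_scheme():
    names = feature_names(13)
    assert names[0] == "AA1_pssm_1"  # alphabetical col 'A' = PSI-BLAST index 1
    assert names[20] == "AA1_disorder_1"
    assert names[21] == "AA1_aaf_1"
    assert names[26] == "AA1_ss_1"
    assert names[29] == "AA1_sa_1"
    assert parse_feature_name("AA12_pssm_1") == (12, "pssm", 1)
    # the externally reported pssm index for methionine is 13 (PSI-BLAST order)
    m_col = AMINO_ACIDS.index("M")
    assert names[m_col] == "AA1_pssm_13"


def test_x_residue_block_is_zeroed():
    rec = ProteinRecord("p1", "AXA")
    rng = np.random.default_rng(1)
    blocks = assemble_blocks(
        "AXA", rng.normal(size=(3, 20)), rng.random(3),
        np.tile([1.0, 0, 0], (3, 1)), np.tile([1.0, 0], (3, 1)),
    )
    assert np.all(blocks[1] == 0)
    assert np.any(blocks[0] != 0)


# --- dedup -------------------------------------------------------------------

def _toy_samples(window_seqs, labels, w=13):
    rec_len = len(window_seqs)
    from domainsweep.encoding import SampleSet

    return SampleSet(
        X=np.arange(rec_len * 31 * w, dtype=float).reshape(rec_len, 31 * w),
        y=np.asarray(labels),
        protein_ids=["p"] * rec_len,
        centers=np.arange(1, rec_len + 1),
        window_seqs=list(window_seqs),
        w=w,
        feature_names=feature_names(w),
    )


def test_dedupe_exact_duplicates():
    s = _toy_samples(["ACDEFGHIKLMNP"] * 2 + ["KKKKKKKKKKKKK"], [1, 1, 0])
    out = dedupe_samples(s, 1.0)
    assert len(out) == 2
    assert out.window_seqs == ["ACDEFGHIKLMNP", "KKKKKKKKKKKKK"]


def test_dedupe_keeps_distinct_and_cross_label():
    # identical windows with different labels are both retained
    s = _toy_samples(["ACDEFGHIKLMNP", "ACDEFGHIKLMNP"], [1, 0])
    assert len(dedupe_samples(s, 1.0)) == 2


def test_dedupe_near_identical_threshold():
    a = "ACDEFGHIKLMNP"
    b = "ACDEFGHIKLMNQ"  # 12/13 = 0.923 identity
    s = _toy_samples([a, b], [1, 1])
    assert len(dedupe_samples(s, 0.9)) == 1  # 0.923 >= 0.9 -> dropped
    assert len(dedupe_samples(s, 0.95)) == 2  # 0.923 < 0.95 -> kept


def test_dedupe_x_never_matches():
    a = "XCDEFGHIKLMNP"
    s = _toy_samples([a, a], [1, 1])
    # only 12 comparable positions match => identity 12/13 < 1.0
    assert len(dedupe_samples(s, 1.0)) == 2
    assert len(dedupe_samples(s, 0.9)) == 1
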