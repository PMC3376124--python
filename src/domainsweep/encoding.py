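"""Per-residue feature blocks and labeled sliding-window samples.

Each residue is described by 31 features: 20 PSSM conservation scores,
1 intrinsic-disorder score, 5 amino-acid factors (Atchley et al.'s
standardized summaries of physicochemical properties), a one-hot
3-state secondary-structure call (helix, strand, other) and a one-hot
2-state solvent accessibility (buried, exposed). A window of w residues
centered on the classified residue is flattened subsite-major into a
31*w feature vector; window positions falling outside the sequence are
padded with the nominal residue 'X', whose feature block is all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AMINO_ACIDS, PSIBLAST_ORDER, ProteinRecord

BLOCK_SIZE = 31  # 20 pssm + 1 disorder + 5 aafactor + 3 ss + 2 sa

# Atchley et al. factor scores: five standardized numeric summaries per
# amino acid — (I) polarity, (II) secondary structure, (III) molecular
# volume, (IV) codon diversity, (V) electrostatic charge.
ATCHLEY_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}


def atchley_factors(residue: str) -> tuple[float, float, float, float, float]:
    """Return the five Atchley factor scores for an amino acid.

    The nominal residue 'X' maps to the all-zero quintuple (the padding
    convention: unknown context contributes nothing).
    """
    if residue == "X":
        return (0.0, 0.0, 0.0, 0.0, 0.0)
    try:
        return ATCHLEY_FACTORS[residue]
    except KeyError:
        raise ValueError(f"unknown amino-acid code: {residue!r}") from None


# pssm feature-name indices follow the PSI-BLAST column convention
# (pssm_13 = M, pssm_1 = A, ...) even though the internal column layout
# is alphabetical; this keeps externally reported feature ids addressable.
_PSSM_NAME_INDEX = {aa: PSIBLAST_ORDER.index(aa) + 1 for aa in AMINO_ACIDS}

_BLOCK_FEATURE_NAMES: list[str] = (
    [f"pssm_{_PSSM_NAME_INDEX[aa]}" for aa in AMINO_ACIDS]
    + ["disorder_1"]
    + [f"aaf_{i}" for i in range(1, 6)]
    + [f"ss_{i}" for i in range(1, 4)]
    + [f"sa_{i}" for i in range(1, 3)]
)


def feature_names(w: int) -> list[str]:
    """Names of the 31*w window features, subsite-major: "AA<subsite>_<feature>"."""
    return [f"AA{s}_{name}" for s in range(1, w + 1) for name in _BLOCK_FEATURE_NAMES]


def parse_feature_name(name: str) -> tuple[int, str, int]:
    """Split "AA<subsite>_<type>_<index>" into (subsite, type, index)."""
    subsite_part, ftype, idx = name.split("_")
    if not subsite_part.startswith("AA"):
        raise ValueError(f"malformed feature name: {name!r}")
    return int(subsite_part[2:]), ftype, int(idx)


def pssm_feature_amino_acid(index: int) -> str:
    """The amino acid a pssm feature index (1..20) refers to."""
    return PSIBLAST_ORDER[index - 1]


def assemble_blocks(
    sequence: str,
    pssm: np.ndarray,
    disorder: np.ndarray,
    ss: np.ndarray,
    sa: np.ndarray,
) -> np.ndarray:
    """Stack per-residue features into an (L, 31) block matrix.

    Column order within a block: pssm[20] (alphabetical amino-acid
    columns), disorder, aafactor[5], ss[3], sa[2]. Rows for the nominal
    residue 'X' are forced to all zeros.
    """
    L = len(sequence)
    for arr, ncol, what in ((pssm, 20, "pssm"), (ss, 3, "ss"), (sa, 2, "sa")):
        arr = np.asarray(arr)
        if arr.shape != (L, ncol):
            raise ValueError(f"{what} must have shape ({L},{ncol}), got {arr.shape}")
    if np.asarray(disorder).shape != (L,):
        raise ValueError(f"disorder must have shape ({L},)")
    aaf = np.array([atchley_factors(ch) for ch in sequence])
    blocks = np.hstack(
        [
            np.asarray(pssm, dtype=float),
            np.asarray(disorder, dtype=float)[:, None],
            aaf,
            np.asarray(ss, dtype=float),
            np.asarray(sa, dtype=float),
        ]
    )
    x_mask = np.array([ch == "X" for ch in sequence])
    blocks[x_mask] = 0.0
    return blocks


@dataclass
class SampleSet:
    """Labeled window samples for one or more proteins.

    Attributes
    ----------
    X : (n, 31*w) float array — flattened window vectors, subsite-major.
    y : (n,) int array — 1 for domain (positive), 0 for non-domain.
    protein_ids, centers : per-sample provenance (1-based center position).
    window_seqs : the w-residue string under each window (with 'X' padding);
        used by identity-based deduplication.
    w : window size; feature_names : the 31*w column names.
    """

    X: np.ndarray
    y: np.ndarray
    protein_ids: list[str]
    centers: np.ndarray
    window_seqs: list[str]
    w: int
    feature_names: list[str]

    def __post_init__(self) -> None:
        if self.X.shape[1] != BLOCK_SIZE * self.w:
            raise ValueError(
                f"vector length {self.X.shape[1]} != 31*w = {BLOCK_SIZE * self.w}"
            )
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return self.X.shape[0]


def label_residues(protein: ProteinRecord) -> np.ndarray:
    """Per-residue boolean labels: True iff covered by a domain interval."""
    labels = np.zeros(len(protein.sequence), dtype=bool)
    for start, end in protein.domains:
        labels[start - 1 : end] = True
    return labels


def make_windows(protein: ProteinRecord, blocks: np.ndarray, w: int) -> SampleSet:
    """Build one labeled window sample per residue of a protein.

    The window of w residues is centered on the classified residue;
    positions outside [1, L] carry the all-zero 'X' block. The label is
    the center residue's domain membership.
    """
    if w % 2 == 0 or w < 1:
        raise ValueError(f"window size must be odd and positive, got {w}")
    L = len(protein.sequence)
    blocks = np.asarray(blocks, dtype=float)
    if blocks.shape != (L, BLOCK_SIZE):
        raise ValueError(f"blocks must have shape ({L},{BLOCK_SIZE}), got {blocks.shape}")
    half = w // 2
    padded = np.vstack(
        [np.zeros((half, BLOCK_SIZE)), blocks, np.zeros((half, BLOCK_SIZE))]
    )
    padded_seq = "X" * half + protein.sequence + "X" * half
    X = np.empty((L, BLOCK_SIZE * w))
    window_seqs = []
    for i in range(L):
        X[i] = padded[i : i + w].ravel()
        window_seqs.append(padded_seq[i : i + w])
    labels = label_residues(protein)
    return SampleSet(
        X=X,
        y=labels.astype(int),
        protein_ids=[protein.id] * L,
        centers=np.arange(1, L + 1),
        window_seqs=window_seqs,
        w=w,
        feature_names=feature_names(w),
    )


def concat_sample_sets(sets: list[SampleSet]) -> SampleSet:
    """Concatenate sample sets that share a window size."""
    if not sets:
        raise ValueError("no sample sets to concatenate")
    w = sets[0].w
    if any(s.w != w for s in sets):
        raise ValueError("window sizes differ")
    return SampleSet(
        X=np.vstack([s.X for s in sets]),
        y=np.concatenate([s.y for s in sets]),
        protein_ids=[pid for s in sets for pid in s.protein_ids],
        centers=np.concatenate([s.centers for s in sets]),
        window_seqs=[ws for s in sets for ws in s.window_seqs],
        w=w,
        feature_names=sets[0].feature_names,
    )


def _subset(samples: SampleSet, keep: list[int]) -> SampleSet:
    return SampleSet(
        X=samples.X[keep],
        y=samples.y[keep],
        protein_ids=[samples.protein_ids[i] for i in keep],
        centers=samples.centers[keep],
        window_seqs=[samples.window_seqs[i] for i in keep],
        w=samples.w,
        feature_names=samples.feature_names,
    )


def dedupe_samples(samples: SampleSet, identity_threshold: float = 1.0) -> SampleSet:
    """Remove windows too similar to an earlier window of the same label.

    A greedy single-linkage scan in input order: a sample is dropped if
    its w-residue window string has identity >= ``identity_threshold``
    (matching positions / w; 'X' never matches anything, itself
    included) to any already-retained sample with the same label.
    Threshold 1.0 degenerates to exact-duplicate removal ('X'-free
    identical strings). This is a deliberately simple stand-in for
    production sequence clustering.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    w = samples.w

    if identity_threshold == 1.0:
        # identity 1.0 requires all w positions to match and none be 'X'
        seen: set[tuple[int, str]] = set()
        keep = []
        for i, ws in enumerate(samples.window_seqs):
            key = (int(samples.y[i]), ws)
            if "X" not in ws and key in seen:
                continue
            seen.add(key)
            keep.append(i)
        return _subset(samples, keep)

    retained: dict[int, list[np.ndarray]] = {0: [], 1: []}
    keep = []
    cutoff = identity_threshold * w
    for i, ws in enumerate(samples.window_seqs):
        arr = np.frombuffer(ws.encode("ascii"), dtype=np.uint8).copy()
        x_mask = arr == ord("X")
        arr_cmp = arr.copy()
        arr_cmp[x_mask] = 0  # 'X' never matches, including another 'X'
        label = int(samples.y[i])
        dropped = False
        for other in retained[label]:
            matches = np.count_nonzero((arr_cmp == other) & (arr_cmp != 0))
            if matches >= cutoff:
                dropped = True
                break
        if not dropped:
            retained[label].append(arr_cmp)
            keep.append(i)
    return _subset(samples, keep)
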