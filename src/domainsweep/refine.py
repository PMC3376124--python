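"""Run-length scanning refinement of per-residue domain predictions.

Per-residue classifier output is written as a code track: '1' for a
predicted domain residue, '2' for non-domain. Isolated mispredictions
show up as short runs of one code inside a long run of the other; a
single left-to-right scan repairs them:

(i)  a '2' is flipped to '1' when it follows a run of more than four
     continuous '1' codes and is followed by fewer than four continuous
     '2' codes;
(ii) a '1' is flipped to '2' when it follows a run of more than four
     continuous '2' codes and is followed by fewer than three
     continuous '1' codes.

"More than four" is read as >= 5 and the "fewer than" bounds as <= 3
and <= 2 respectively. The preceding run is measured on the working
(already-modified) track, so earlier flips can extend it; the following
run starts at the next position and, since the scan only modifies
positions already passed, equals the run in the original track. The
maximal runs of '1' remaining after the scan are the predicted domain
regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ifs import ConfusionCounts

DOMAIN_CODE = "1"
LINKER_CODE = "2"


@dataclass
class CodeTrack:
    """A per-residue prediction string over {'1','2'} for one protein."""

    protein_id: str
    codes: str

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError(f"{self.protein_id}: empty code track")
        bad = set(self.codes) - {DOMAIN_CODE, LINKER_CODE}
        if bad:
            raise ValueError(f"{self.protein_id}: invalid codes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.codes)


def codes_from_predictions(protein_id: str, is_domain) -> CodeTrack:
    """Encode per-residue boolean/0-1 predictions as a '1'/'2' track."""
    arr = np.asarray(is_domain).astype(bool)
    return CodeTrack(protein_id, "".join(DOMAIN_CODE if v else LINKER_CODE for v in arr))


def _following_runs(codes: str) -> np.ndarray:
    """run[p] = length of the maximal constant run starting at position p."""
    n = len(codes)
    run = np.ones(n, dtype=int)
    for p in range(n - 2, -1, -1):
        if codes[p] == codes[p + 1]:
            run[p] = run[p + 1] + 1
    return run


def refine_track(track: CodeTrack) -> CodeTrack:
    """Apply the scanning refinement in one left-to-right pass.

    At position p the preceding run is measured on the working track
    (cascading: a flip at p-1 can lengthen the run seen at p); the
    following run is measured from p+1 on, where the track is still the
    original. The examined position never counts toward its own
    following run.
    """
    codes = list(track.codes)
    n = len(codes)
    # follow[p]-1 = same-code run length after p; valid during the scan
    # because positions > p are still unmodified when p is examined
    follow = _following_runs(track.codes)
    prev_run = 0  # length of the constant run ending at p-1 on the working track
    for p in range(n):
        cur = codes[p]
        if p > 0 and prev_run >= 5 and codes[p - 1] != cur:
            if cur == LINKER_CODE and follow[p] - 1 <= 3:
                codes[p] = DOMAIN_CODE
            elif cur == DOMAIN_CODE and follow[p] - 1 <= 2:
                codes[p] = LINKER_CODE
        # update the preceding-run length for position p+1 on the working track
        if p > 0 and codes[p] == codes[p - 1]:
            prev_run += 1
        else:
            prev_run = 1
    return CodeTrack(track.protein_id, "".join(codes))


def extract_regions(track: CodeTrack) -> list[tuple[int, int]]:
    """Maximal runs of '1' as 1-based inclusive (start, end) intervals."""
    regions: list[tuple[int, int]] = []
    start = None
    for i, c in enumerate(track.codes, start=1):
        if c == DOMAIN_CODE and start is None:
            start = i
        elif c != DOMAIN_CODE and start is not None:
            regions.append((start, i - 1))
            start = None
    if start is not None:
        regions.append((start, len(track.codes)))
    return regions


def track_from_regions(protein_id: str, length: int, regions) -> CodeTrack:
    """Inverse of :func:`extract_regions` for a known protein length."""
    arr = np.full(length, LINKER_CODE)
    for start, end in regions:
        if not 1 <= start <= end <= length:
            raise ValueError(f"region ({start},{end}) outside [1,{length}]")
        arr[start - 1 : end] = DOMAIN_CODE
    return CodeTrack(protein_id, "".join(arr))


def evaluate_tracks(predicted: CodeTrack, truth) -> ConfusionCounts:
    """Per-residue confusion counts of a track against boolean truth labels."""
    truth = np.asarray(truth).astype(bool)
    if len(predicted.codes) != truth.size:
        raise ValueError(
            f"{predicted.protein_id}: track length {len(predicted.codes)} != "
            f"truth length {truth.size}"
        )
    pred = np.frombuffer(predicted.codes.encode(), dtype=np.uint8) == ord(DOMAIN_CODE)
    return ConfusionCounts.from_predictions(truth, pred)
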