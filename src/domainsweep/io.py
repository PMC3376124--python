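"""Readers and writers for the external formats the pipeline touches.

All coordinates in files and in :class:`ProteinRecord` are 1-based inclusive
residue positions; internal numpy arrays are 0-based. Writers emit UTF-8
tab-separated text with a header line.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 amino acids in the canonical internal (alphabetical) column order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: PSI-BLAST's conventional residue column order; the externally reported pssm
#: feature indices (pssm_1 .. pssm_20) refer to positions in this string.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"

_ALPHABET = set(AMINO_ACIDS) | {"X"}


@dataclass
class ProteinRecord:
    """A protein sequence with its annotated domain intervals.

    Parameters
    ----------
    id : str
        Accession / identifier, unique within a dataset.
    sequence : str
        Uppercase sequence over the 20 amino acids plus the nominal
        residue ``'X'``.
    domains : list of (int, int)
        Sorted, non-overlapping 1-based inclusive residue intervals.
    """

    id: str
    sequence: str
    domains: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: sequence contains invalid characters {sorted(bad)}"
            )
        self.domains = [(int(s), int(e)) for s, e in self.domains]
        prev_end = 0
        for start, end in self.domains:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(
                    f"{self.id}: interval ({start},{end}) outside "
                    f"[1,{len(self.sequence)}]"
                )
            if start <= prev_end:
                raise ValueError(
                    f"{self.id}: intervals overlap or are unsorted at "
                    f"({start},{end})"
                )
            prev_end = end

    def __len__(self) -> int:
        return len(self.sequence)


def _clean_sequence(raw: str, rec_id: str) -> str:
    seq = raw.upper()
    cleaned = []
    replaced = 0
    for ch in seq:
        if ch in _ALPHABET:
            cleaned.append(ch)
        else:
            cleaned.append("X")
            replaced += 1
    if replaced:
        logger.warning(
            "%s: replaced %d non-standard residue(s) with 'X'", rec_id, replaced
        )
    return "".join(cleaned)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects (domains empty).

    Sequences are uppercased; characters outside the 20-letter alphabet
    plus 'X' are replaced by 'X' with a logged warning. Empty files and
    duplicate ids are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id: {entry.id}")
        seen.add(entry.id)
        records.append(ProteinRecord(entry.id, _clean_sequence(str(entry.seq), entry.id)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent 1-based inclusive intervals."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def read_domain_annotations(path, proteins: list[ProteinRecord]) -> list[ProteinRecord]:
    """Attach domain intervals from a TSV of (protein_id, start, end) rows.

    Intervals are 1-based inclusive; overlapping or adjacent rows for the
    same protein are merged. Rows referencing unknown proteins, or with
    start > end or end beyond the sequence, raise ``ValueError`` naming
    the offending row.
    """
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "start", "end"}
    if not required.issubset(table.columns):
        raise ValueError(f"annotation TSV must have columns {sorted(required)}")
    by_id = {p.id: p for p in proteins}
    intervals: dict[str, list[tuple[int, int]]] = {p.id: [] for p in proteins}
    for row_num, row in enumerate(table.itertuples(index=False), start=2):
        pid, start, end = row.protein_id, int(row.start), int(row.end)
        if pid not in by_id:
            raise ValueError(f"row {row_num}: unknown protein id {pid!r}")
        if start > end:
            raise ValueError(f"row {row_num}: start {start} > end {end}")
        if start < 1 or end > len(by_id[pid].sequence):
            raise ValueError(
                f"row {row_num}: interval ({start},{end}) outside "
                f"[1,{len(by_id[pid].sequence)}] for {pid}"
            )
        intervals[pid].append((start, end))
    return [
        ProteinRecord(p.id, p.sequence, merge_intervals(intervals[p.id]))
        for p in proteins
    ]


_PSSM_ROW = re.compile(r"^\s*(\d+)\s+([A-Za-z])((?:\s+-?\d+)+)\s*$")


def read_pssm_ascii(path, expected_length: int | None = None,
                    columns: str = "scores") -> np.ndarray:
    """Parse a PSI-BLAST ASCII position-specific scoring matrix.

    The dialect: free-form header lines, a column-header line naming the
    20 residue columns, one row per sequence position starting with the
    position index and the query residue, then at least 20 integer
    columns (log-odds scores, optionally followed by 20 weighted
    percentages and trailing statistics), and a trailing statistics
    block that is ignored.

    Parameters
    ----------
    path : path-like
        File to parse.
    expected_length : int, optional
        Declared sequence length; a mismatch in parsed row count raises.
    columns : {"scores", "percentages"}
        Which 20-column group to return. PSI-BLAST prints log-odds
        scores first and weighted observed percentages second; the
        log-odds scores are the default conservation features.

    Returns
    -------
    numpy.ndarray of shape (L, 20)
        Rows in sequence order; columns remapped from the file's header
        order to the canonical alphabetical order ``AMINO_ACIDS``.
    """
    if columns not in ("scores", "percentages"):
        raise ValueError("columns must be 'scores' or 'percentages'")
    header_order: list[str] | None = None
    rows: list[list[int]] = []
    expected_pos = 1
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if header_order is None:
                tokens = line.split()
                if len(tokens) >= 20 and all(
                    len(t) == 1 and t in AMINO_ACIDS for t in tokens[:20]
                ):
                    header_order = tokens[:20]
                continue
            m = _PSSM_ROW.match(line)
            if m is None:
                if rows and line.strip():
                    break  # trailing statistics block
                if line.strip() and line.split()[0].isdigit():
                    raise ValueError(f"malformed PSSM row: {line.rstrip()!r}")
                continue
            pos = int(m.group(1))
            values = [int(v) for v in m.group(3).split()]
            if len(values) < 20:
                raise ValueError(
                    f"PSSM row {pos}: expected >=20 score columns, got {len(values)}"
                )
            if pos != expected_pos:
                raise ValueError(
                    f"PSSM rows out of order: expected position {expected_pos}, got {pos}"
                )
            expected_pos += 1
            if columns == "percentages":
                if len(values) < 40:
                    raise ValueError(
                        f"PSSM row {pos}: no percentage columns present"
                    )
                rows.append(values[20:40])
            else:
                rows.append(values[:20])
    if header_order is None:
        raise ValueError(f"no residue column header found in {path}")
    if not rows:
        raise ValueError(f"no PSSM rows parsed from {path}")
    if expected_length is not None and len(rows) != expected_length:
        raise ValueError(
            f"PSSM has {len(rows)} rows but sequence length is {expected_length}"
        )
    matrix = np.asarray(rows, dtype=float)
    # remap file header order -> canonical alphabetical order
    col_index = {aa: i for i, aa in enumerate(header_order)}
    order = [col_index[aa] for aa in AMINO_ACIDS]
    return matrix[:, order]


_SS_STATES = {"H": 0, "E": 1, "O": 2}
_SA_STATES = {"B": 0, "E": 1}


def read_residue_table(path, kind: str, proteins: list[ProteinRecord] | None = None):
    """Read a per-residue value TSV of (protein_id, position, value).

    Parameters
    ----------
    kind : {"disorder", "ss", "sa"}
        ``disorder``: real value in [0,1] -> per-protein float vector of
        shape (L,). ``ss``: 3-state symbol in {H,E,O} -> one-hot (L,3)
        in (helix, strand, other) order. ``sa``: 2-state symbol in
        {B,E} -> one-hot (L,2) in (buried, exposed) order.
    proteins : list of ProteinRecord, optional
        When given, every position 1..L of every protein must be
        present; otherwise the length is inferred from the maximum
        position per protein.

    Returns
    -------
    dict mapping protein_id -> numpy.ndarray
    """
    if kind not in ("disorder", "ss", "sa"):
        raise ValueError(f"unknown residue table kind: {kind!r}")
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"residue TSV must have columns {sorted(required)}")

    values: dict[str, dict[int, object]] = {}
    for row_num, row in enumerate(table.itertuples(index=False), start=2):
        pid, pos = row.protein_id, int(row.position)
        if pos < 1:
            raise ValueError(f"row {row_num}: position {pos} < 1")
        if kind == "disorder":
            v = float(row.value)
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"row {row_num}: disorder score {v} outside [0,1]"
                )
        else:
            v = str(row.value).strip()
            states = _SS_STATES if kind == "ss" else _SA_STATES
            if v not in states:
                raise ValueError(
                    f"row {row_num}: unknown {kind} state symbol {v!r}"
                )
        values.setdefault(pid, {})
        if pos in values[pid]:
            raise ValueError(f"row {row_num}: duplicate position {pos} for {pid}")
        values[pid][pos] = v

    lengths: dict[str, int] = {}
    if proteins is not None:
        known = {p.id for p in proteins}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown protein ids in {kind} table: {sorted(unknown)}")
        lengths = {p.id: len(p.sequence) for p in proteins}
    else:
        lengths = {pid: max(pos) for pid, pos in values.items()}

    out: dict[str, np.ndarray] = {}
    for pid, length in lengths.items():
        per_pos = values.get(pid, {})
        missing = [p for p in range(1, length + 1) if p not in per_pos]
        if missing:
            raise ValueError(
                f"{kind} table for {pid}: missing positions {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        if kind == "disorder":
            out[pid] = np.array([per_pos[p] for p in range(1, length + 1)], dtype=float)
        else:
            states = _SS_STATES if kind == "ss" else _SA_STATES
            arr = np.zeros((length, len(states)), dtype=float)
            for p in range(1, length + 1):
                arr[p - 1, states[per_pos[p]]] = 1.0
            out[pid] = arr
    return out


def write_regions(regions: dict[str, list[tuple[int, int]]], path) -> None:
    """Write per-protein (start, end) regions as a TSV.

    Round-trips through :func:`read_domain_annotations` (coordinates are
    1-based inclusive). An empty mapping yields a header-only file.
    """
    rows = [
        {"protein_id": pid, "start": start, "end": end}
        for pid, intervals in regions.items()
        for start, end in intervals
    ]
    pd.DataFrame(rows, columns=["protein_id", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def write_fasta(records: list[ProteinRecord], path) -> None:
    """Write records as plain FASTA (60-column wrapped)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def write_residue_table(values: dict[str, np.ndarray], kind: str, path) -> None:
    """Write per-residue values in the format read_residue_table expects."""
    if kind not in ("disorder", "ss", "sa"):
        raise ValueError(f"unknown residue table kind: {kind!r}")
    rows = []
    for pid, arr in values.items():
        for i in range(len(arr)):
            if kind == "disorder":
                v = f"{float(arr[i]):.6g}"
            elif kind == "ss":
                v = "HEO"[int(np.argmax(arr[i]))]
            else:
                v = "BE"[int(np.argmax(arr[i]))]
            rows.append({"protein_id": pid, "position": i + 1, "value": v})
    pd.DataFrame(rows, columns=["protein_id", "position", "value"]).to_csv(
        path, sep="\t", index=False
    )
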