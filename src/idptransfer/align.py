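"""Family alignment, identity-to-reference filtering and coordinate mapping.

Production alignments go through external aligner adapters (MAFFT, Clustal
Omega) run with each tool's defaults.  A deterministic built-in progressive
aligner (k-mer/UPGMA guide tree, profile-profile dynamic programming with
affine gaps) is always available so the whole pipeline runs with no external
binaries.

Two distinct identity definitions are used on purpose:

* :func:`pairwise_identity` — identical pairs / full alignment length
  (including gap columns); used for redundancy clustering of reference
  proteins.
* :func:`identity_to_reference` — identical pairs / reference non-gap
  columns; used for all MSA row filtering.  Deletions in an ortholog lower
  its score because fidelity to the annotated reference positions is what
  is being measured.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

from .io import GAP, Msa, ProteinRecord, write_fasta, read_msa

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_RES_INDEX = {c: i for i, c in enumerate(ALPHABET)}

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


class AlignerNotFoundError(RuntimeError):
    """An external aligner binary could not be resolved."""


@dataclass
class AlignerSpec:
    """Which aligner to use and any extra command-line options."""

    method: Literal["clustal-omega", "mafft", "builtin"] = "builtin"
    options: dict = field(default_factory=dict)


def substitution_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Dense substitution-score matrix over :data:`ALPHABET`."""
    m = substitution_matrices.load(name)
    s = np.zeros((len(ALPHABET), len(ALPHABET)))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            s[i, j] = m[a][b]
    return s


def encode(sequence: str) -> np.ndarray:
    """Sequence → integer codes over :data:`ALPHABET` (gap excluded)."""
    try:
        return np.array([_RES_INDEX[c] for c in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue {exc} not in alphabet") from exc


# ---------------------------------------------------------------------------
# pairwise identity (clustering definition)
# ---------------------------------------------------------------------------

def _pairwise_aligner(gap_open: float = DEFAULT_GAP_OPEN,
                      gap_extend: float = DEFAULT_GAP_EXTEND) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity under a global alignment.

    Identical residue pairs divided by the full alignment length, gap
    columns included — the definition used for redundancy clustering.
    """
    aligner = _pairwise_aligner()
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    matches = sum(a == b and a != GAP for a, b in zip(row_a, row_b))
    return 100.0 * matches / len(row_a)


# ---------------------------------------------------------------------------
# built-in progressive aligner
# ---------------------------------------------------------------------------

def _kmer_profile(seq: str, k: int = 3) -> dict[str, int]:
    prof: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        prof[kmer] = prof.get(kmer, 0) + 1
    if not prof:  # sequence shorter than k
        prof[seq] = 1
    return prof


def _cosine_distance(pa: dict[str, int], pb: dict[str, int]) -> float:
    dot = sum(v * pb.get(kmer, 0) for kmer, v in pa.items())
    na = sum(v * v for v in pa.values()) ** 0.5
    nb = sum(v * v for v in pb.values()) ** 0.5
    if na == 0 or nb == 0:
        return 1.0
    return 1.0 - dot / (na * nb)


def _guide_tree(sequences: Sequence[str], k: int = 3) -> np.ndarray:
    """UPGMA linkage over pairwise k-mer cosine distances."""
    profiles = [_kmer_profile(s, k) for s in sequences]
    n = len(sequences)
    condensed = np.array(
        [
            _cosine_distance(profiles[i], profiles[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
    )
    return linkage(condensed, method="average")


def _profile(rows: list[np.ndarray], n_letters: int) -> np.ndarray:
    """Column frequency profile; gaps contribute zero residue mass."""
    width = rows[0].size
    prof = np.zeros((width, n_letters))
    for row in rows:
        nz = row >= 0
        np.add.at(prof, np.nonzero(nz)[0], np.eye(n_letters)[row[nz]])
    return prof / len(rows)


def _align_profiles(
    rows_a: list[np.ndarray],
    rows_b: list[np.ndarray],
    sub: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Global affine-gap DP between two profiles (rows are gap=-1 int codes)."""
    n, m = rows_a[0].size, rows_b[0].size
    prof_a = _profile(rows_a, sub.shape[0])
    prof_b = _profile(rows_b, sub.shape[0])
    score = prof_a @ sub @ prof_b.T  # (n, m) expected substitution score

    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)  # gap in B (consumes A)
    Iy = np.full((n + 1, m + 1), neg)  # gap in A (consumes B)
    M[0, 0] = 0.0
    j_idx = np.arange(m + 1)
    # row 0: only Iy states reachable
    u0 = M[0] + gap_extend * j_idx
    acc0 = np.maximum.accumulate(u0)
    Iy[0, 1:] = acc0[:-1] - gap_open - gap_extend * (j_idx[1:] - 1)
    for i in range(1, n + 1):
        Ix[i] = np.maximum(M[i - 1] - gap_open, Ix[i - 1] - gap_extend)
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = score[i - 1] + best_prev[:-1]
        u = np.maximum(M[i], Ix[i]) + gap_extend * j_idx
        acc = np.maximum.accumulate(u)
        Iy[i, 1:] = acc[:-1] - gap_open - gap_extend * (j_idx[1:] - 1)

    # traceback (prefer M, then Ix, then Iy on exact ties)
    tol = 1e-9
    i, j = n, m
    finals = (M[n, m], Ix[n, m], Iy[n, m])
    state = int(np.argmax(finals))
    cols: list[tuple[int, int]] = []  # (a column or -1, b column or -1)
    while i > 0 or j > 0:
        if state == 0:
            cols.append((i - 1, j - 1))
            prev = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:
            cols.append((i - 1, -1))
            if M[i - 1, j] - gap_open >= Ix[i, j] - tol:
                state = 0
            i -= 1
        else:
            cols.append((-1, j - 1))
            opened = np.maximum(M[i, j - 1], Ix[i, j - 1]) - gap_open
            if opened >= Iy[i, j] - tol:
                state = 0 if M[i, j - 1] >= Ix[i, j - 1] else 1
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    cols.reverse()

    a_cols = np.array([c[0] for c in cols])
    b_cols = np.array([c[1] for c in cols])
    new_a = [
        np.where(a_cols >= 0, row[np.clip(a_cols, 0, None)], -1) for row in rows_a
    ]
    new_b = [
        np.where(b_cols >= 0, row[np.clip(b_cols, 0, None)], -1) for row in rows_b
    ]
    return new_a, new_b


def builtin_progressive_align(
    records: Sequence[ProteinRecord],
    reference_id: str,
    sub_matrix: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Msa:
    """Deterministic progressive alignment.

    Guide tree: UPGMA over 3-mer cosine distances.  Profiles are merged by
    global dynamic programming with affine gaps on expected substitution
    scores.  With two sequences this reduces to plain pairwise global
    alignment.
    """
    if len(records) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    ids = [r.accession for r in records]
    if reference_id not in ids:
        raise ValueError(f"reference {reference_id!r} not among records")
    sub = substitution_matrix(sub_matrix)
    encoded = [encode(r.sequence) for r in records]

    if len(records) == 2:
        a, b = _align_profiles([encoded[0]], [encoded[1]], sub, gap_open, gap_extend)
        node_rows = a + b
        node_members = [0, 1]
    else:
        tree = _guide_tree([r.sequence for r in records])
        n = len(records)
        nodes: dict[int, tuple[list[int], list[np.ndarray]]] = {
            i: ([i], [encoded[i]]) for i in range(n)
        }
        for step, (left, right, _dist, _cnt) in enumerate(tree):
            mem_l, rows_l = nodes.pop(int(left))
            mem_r, rows_r = nodes.pop(int(right))
            new_l, new_r = _align_profiles(rows_l, rows_r, sub, gap_open, gap_extend)
            nodes[n + step] = (mem_l + mem_r, new_l + new_r)
        (node_members, node_rows), = nodes.values()

    # back to strings, restored to input row order
    by_member = dict(zip(node_members, node_rows))
    rows = []
    for i in range(len(records)):
        codes = by_member[i]
        rows.append("".join(GAP if c < 0 else ALPHABET[c] for c in codes))
    msa = Msa(
        row_ids=ids,
        rows=rows,
        reference_id=reference_id,
        metadata={"method": "builtin", "sub_matrix": sub_matrix,
                  "gap_open": gap_open, "gap_extend": gap_extend},
    )
    _check_ungap(msa, records)
    return msa


def _check_ungap(msa: Msa, records: Sequence[ProteinRecord]) -> None:
    by_id = {r.accession: r.sequence for r in records}
    for row_id in msa.row_ids:
        if msa.ungapped(row_id) != by_id[row_id]:
            raise RuntimeError(f"aligner mutated sequence {row_id!r}")


# ---------------------------------------------------------------------------
# external aligner adapters
# ---------------------------------------------------------------------------

def _run_external(records: Sequence[ProteinRecord], method: str,
                  options: dict) -> list[tuple[str, str]]:
    binary = {"mafft": "mafft", "clustal-omega": "clustalo"}[method]
    if shutil.which(binary) is None:
        raise AlignerNotFoundError(
            f"{binary!r} not found on PATH; install it or use "
            "AlignerSpec(method='builtin')"
        )
    extra = [str(x) for kv in options.items() for x in kv if x != ""]
    with tempfile.TemporaryDirectory() as tmp:
        fasta_in = Path(tmp) / "in.fasta"
        fasta_out = Path(tmp) / "out.fasta"
        write_fasta(records, fasta_in)
        if method == "mafft":
            with open(fasta_out, "w") as out:
                subprocess.run(
                    ["mafft", "--quiet", "--anysymbol", *extra, str(fasta_in)],
                    stdout=out, stderr=subprocess.DEVNULL, check=True,
                )
        else:
            subprocess.run(
                ["clustalo", "--force", "-i", str(fasta_in), "-o", str(fasta_out),
                 *extra],
                check=True,
            )
        aln = read_msa(fasta_out, "afa")
    return list(zip(aln.row_ids, aln.rows))


def align_family(
    records: Sequence[ProteinRecord],
    reference_id: str,
    spec: AlignerSpec | None = None,
) -> Msa:
    """Align one ortholog family with the requested aligner.

    The returned alignment preserves the input row order, records the
    method in its metadata, and is checked to reproduce every input
    sequence exactly when ungapped.
    """
    spec = spec or AlignerSpec()
    if len(records) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    ids = [r.accession for r in records]
    if reference_id not in ids:
        raise ValueError(f"reference {reference_id!r} not among records")
    if spec.method == "builtin":
        return builtin_progressive_align(records, reference_id)
    pairs = dict(_run_external(records, spec.method, spec.options))
    msa = Msa(
        row_ids=ids,
        rows=[pairs[i] for i in ids],
        reference_id=reference_id,
        metadata={"method": spec.method},
    )
    _check_ungap(msa, records)
    return msa


# ---------------------------------------------------------------------------
# identity to reference, row filtering
# ---------------------------------------------------------------------------

def identity_to_reference(
    msa: Msa, row_id: str, columns: tuple[int, int] | None = None
) -> float:
    """Percent identity of a row to the reference row.

    Denominator: alignment columns (within ``columns``, 1-based inclusive,
    when given) where the reference is not a gap.  A gap in the row
    opposite a reference residue counts as a mismatch.
    """
    ref = msa.reference_row
    other = msa.row(row_id)
    if columns is None:
        lo, hi = 0, msa.width
    else:
        if not (1 <= columns[0] <= columns[1] <= msa.width):
            raise ValueError(f"column range {columns} out of bounds")
        lo, hi = columns[0] - 1, columns[1]
    ref_w, other_w = ref[lo:hi], other[lo:hi]
    denom = sum(c != GAP for c in ref_w)
    if denom == 0:
        raise ValueError("reference is all-gap in the requested range")
    matches = sum(a == b and a != GAP for a, b in zip(ref_w, other_w))
    return 100.0 * matches / denom


def drop_low_identity_rows(
    msa: Msa, threshold: float, columns: tuple[int, int] | None = None
) -> Msa:
    """Remove rows below ``threshold`` percent identity to the reference.

    The reference row is always retained; gap-only columns that result are
    removed afterwards.  Idempotent, and monotone in the threshold.
    """
    if not (0 < threshold <= 100):
        raise ValueError("threshold must be in (0, 100]")
    keep = [
        row_id
        for row_id in msa.row_ids
        if row_id == msa.reference_id
        or identity_to_reference(msa, row_id, columns) >= threshold
    ]
    return msa.select_rows(keep).drop_gap_only_columns()


# ---------------------------------------------------------------------------
# coordinate maps
# ---------------------------------------------------------------------------

class CoordinateMap:
    """Bidirectional residue-position ↔ alignment-column map, per row.

    Positions and columns are both 1-based; ``column_to_seq`` returns
    ``None`` for gap columns.
    """

    def __init__(self, msa: Msa):
        self._pos2col: dict[str, np.ndarray] = {}
        self._col2pos: dict[str, np.ndarray] = {}
        for row_id, row in zip(msa.row_ids, msa.rows):
            chars = np.frombuffer(row.encode(), dtype="S1")
            nongap = chars != b"-"
            self._pos2col[row_id] = np.nonzero(nongap)[0] + 1
            col2pos = np.where(nongap, np.cumsum(nongap), 0)
            self._col2pos[row_id] = col2pos

    def seq_to_column(self, row_id: str, pos: int) -> int:
        cols = self._pos2col[row_id]
        if not (1 <= pos <= cols.size):
            raise IndexError(f"position {pos} out of range for {row_id!r}")
        return int(cols[pos - 1])

    def column_to_seq(self, row_id: str, column: int) -> int | None:
        col2pos = self._col2pos[row_id]
        if not (1 <= column <= col2pos.size):
            raise IndexError(f"column {column} out of range")
        pos = int(col2pos[column - 1])
        return pos if pos > 0 else None

    def n_positions(self, row_id: str) -> int:
        return int(self._pos2col[row_id].size)
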