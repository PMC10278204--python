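"""Alignment quality scoring with the normalized mean-distance (NorMD) objective.

NorMD scores an MSA from residue-similarity information alone — no external
reference alignment — by combining the observed pairwise similarity of the
aligned columns with ab initio information about the sequences themselves:
their lengths, compositions and self-similarity.  For each unordered pair of
rows the aligned similarity score (substitution scores over mutually
ungapped columns, minus affine gap penalties) is normalized between the
maximal attainable score for that pair (bounded by the lower of the two
self-alignment scores) and the score expected for unrelated sequences of
the same compositions and lengths:

    normd_pair = (S_pair - S_random) / (S_max - S_random)

and the alignment score is the mean over pairs.  Identical sequences score
1 by construction, mutually random sequences score near 0, and scores above
1 are arithmetically legal.  A score strictly greater than 0.6 is treated
as marking a reliable alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np

from .align import ALPHABET, encode, substitution_matrix
from .io import GAP, Msa

RELIABLE_THRESHOLD = 0.6


@dataclass
class QualityReport:
    """NorMD score and shape of one scored alignment."""

    normd: float
    n_rows: int
    n_columns: int
    scope: Literal["global", "region"] = "global"
    reliable: bool = False
    identity_to_reference: dict[str, float] | None = None


def is_reliable(score: float, threshold: float = RELIABLE_THRESHOLD) -> bool:
    """Strict inequality: a score of exactly ``threshold`` is not reliable."""
    return score > threshold


def _gap_penalty(
    gaps_a: np.ndarray,
    gaps_b: np.ndarray,
    gap_open: float,
    gap_extend: float,
    penalize_terminal: bool,
) -> float:
    """Affine penalty for columns where exactly one row of the pair is gapped."""
    penalty = 0.0
    for gaps, other_gaps in ((gaps_a, gaps_b), (gaps_b, gaps_a)):
        run = gaps & ~other_gaps  # gap opposite a residue
        if not penalize_terminal:
            residues = np.nonzero(~gaps)[0]
            if residues.size == 0:
                continue
            interior = np.zeros_like(run)
            interior[residues[0] : residues[-1] + 1] = True
            run = run & interior
        idx = np.nonzero(run)[0]
        if idx.size == 0:
            continue
        n_opens = 1 + int(np.sum(np.diff(idx) > 1))
        penalty += n_opens * gap_open + (idx.size - n_opens) * gap_extend
    return penalty


def normd_score(
    msa: Msa,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    penalize_terminal_gaps: bool = False,
) -> float:
    """Normalized mean-distance quality score of an alignment.

    Deterministic, invariant to row order.  Raises for single-row or
    zero-column alignments, where the score is undefined.
    """
    if msa.n_rows < 2:
        raise ValueError("NorMD is undefined for a single-row alignment")
    if msa.width < 1:
        raise ValueError("NorMD is undefined for a zero-column alignment")
    sub = substitution_matrix(matrix)
    n_letters = len(ALPHABET)

    codes = []
    for row in msa.rows:
        arr = np.full(len(row), -1, dtype=np.int64)
        nongap = np.frombuffer(row.encode(), dtype="S1") != GAP.encode()
        if nongap.any():
            arr[nongap] = encode(row.replace(GAP, ""))
        codes.append(arr)

    self_scores = []
    comps = []
    lengths = []
    for arr in codes:
        residues = arr[arr >= 0]
        lengths.append(residues.size)
        self_scores.append(float(np.sum(sub[residues, residues])))
        comp = np.bincount(residues, minlength=n_letters).astype(float)
        comps.append(comp / max(residues.size, 1))

    # pairs in row-id-sorted order so the score is exactly row-order invariant
    order = sorted(range(msa.n_rows), key=lambda i: msa.row_ids[i])
    pair_scores = []
    for i, k in combinations(order, 2):
        a, b = codes[i], codes[k]
        both = (a >= 0) & (b >= 0)
        s_pair = float(np.sum(sub[a[both], b[both]]))
        s_pair -= _gap_penalty(
            a < 0, b < 0, gap_open, gap_extend, penalize_terminal_gaps
        )
        s_max = min(self_scores[i], self_scores[k])
        n_min = min(lengths[i], lengths[k])
        s_rand = n_min * float(comps[i] @ sub @ comps[k])
        denom = s_max - s_rand
        if denom <= 0:  # degenerate (e.g. all-X rows); score carries no signal
            pair_scores.append(0.0)
            continue
        pair_scores.append((s_pair - s_rand) / denom)
    return float(np.mean(pair_scores))


def quality_report(
    msa: Msa,
    scope: Literal["global", "region"] = "global",
    threshold: float = RELIABLE_THRESHOLD,
    **normd_kwargs,
) -> QualityReport:
    """Score an alignment and package the result with per-row identities."""
    from .align import identity_to_reference

    score = normd_score(msa, **normd_kwargs)
    identities = {
        row_id: identity_to_reference(msa, row_id)
        for row_id in msa.row_ids
        if row_id != msa.reference_id
    }
    return QualityReport(
        normd=score,
        n_rows=msa.n_rows,
        n_columns=msa.width,
        scope=scope,
        reliable=is_reliable(score, threshold),
        identity_to_reference=identities,
    )
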