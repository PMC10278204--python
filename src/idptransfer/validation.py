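"""Internal validation: annotation overlap between aligned proteins, and
per-residue disorder classification from AlphaFold plDDT confidence.

When an alignment contains two independently annotated proteins, the
projection of the reference region onto the other protein can be compared
with that protein's own curated annotation.  Overlap is reference-
normalized: the fraction of the reference region's alignment columns that
the other protein also annotates (with any term of the same ontology
namespace).  Zero overlap with high identity is expected and meaningful —
curators of the two entries may simply have studied different segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AnnotatedRegion, Msa
from .align import CoordinateMap


@dataclass
class OverlapResult:
    """Overlap of one reference region with another row's annotations."""

    reference_region_id: str
    other_accession: str
    other_region_id: str | None
    overlap_percent: float
    bin: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_percent <= 100.0):
            raise ValueError("overlap_percent outside [0, 100]")


BIN_EDGES = list(range(0, 101, 10))


def decile_bin(value: float) -> str:
    """Left-closed decile label; 100 falls in the top bin."""
    lo = min(int(value // 10) * 10, 90)
    return f"{lo}-{lo + 10}"


def _region_columns(cmap: CoordinateMap, row_id: str, region: AnnotatedRegion,
                    n_positions: int) -> set[int]:
    start = region.start
    end = min(region.end, n_positions)
    if start > n_positions:
        return set()
    return set(
        range(
            cmap.seq_to_column(row_id, start),
            cmap.seq_to_column(row_id, end) + 1,
        )
    )


def annotation_overlap(
    msa: Msa,
    ref_region: AnnotatedRegion,
    other_accession: str,
    other_regions: list[AnnotatedRegion],
) -> OverlapResult:
    """Percent of the reference region's columns annotated in the other row.

    The denominator is always the reference region's column window, so the
    statistic is deliberately asymmetric between the two proteins.  Among
    the other protein's regions, only those in the same ontology namespace
    (GO vs IDPO) compete, and the best-overlapping one is reported.  No
    candidate region means zero overlap, however similar the sequences.
    """
    if ref_region.protein_accession != msa.reference_id:
        raise ValueError("reference region does not belong to the MSA reference row")
    cmap = CoordinateMap(msa)
    ref_cols = _region_columns(
        cmap, msa.reference_id, ref_region, cmap.n_positions(msa.reference_id)
    )
    if not ref_cols:
        raise ValueError("reference region outside the aligned reference row")
    best, best_id = 0.0, None
    n_other = cmap.n_positions(other_accession)
    for region in other_regions:
        if region.ontology != ref_region.ontology:
            continue
        cols = _region_columns(cmap, other_accession, region, n_other)
        overlap = 100.0 * len(ref_cols & cols) / len(ref_cols)
        if overlap > best or best_id is None:
            best, best_id = overlap, region.region_id
    return OverlapResult(
        reference_region_id=ref_region.region_id,
        other_accession=other_accession,
        other_region_id=best_id,
        overlap_percent=best,
        bin=decile_bin(best),
    )


def overlap_distribution(results: list[OverlapResult]) -> dict[str, int]:
    """Decile histogram of overlap percentages; counts sum to the input size."""
    if not results:
        raise ValueError("no overlap results")
    counts = {f"{lo}-{lo + 10}": 0 for lo in range(0, 100, 10)}
    for res in results:
        counts[res.bin] += 1
    return counts


def classify_disorder_plddt(
    values, cutoff: float = 0.7
) -> list[str]:
    """Per-residue order/disorder call from plDDT confidence.

    plDDT below the cutoff marks a residue disordered.  Vectors on the
    0–100 scale (any value above 1.5) are rescaled to 0–1 first.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty plDDT vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("plDDT values must be finite")
    if np.any(arr > 1.5):
        arr = arr / 100.0
    return ["disordered" if v < cutoff else "ordered" for v in arr]
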