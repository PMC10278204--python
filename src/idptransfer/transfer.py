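"""Region-level quality control and annotation transfer.

This is the heart of the pipeline.  Disordered regions evolve fast, so a
family alignment that looks fine globally can be locally unreliable — and
vice versa.  Each annotated region of the reference is therefore chopped
out of the global alignment, realigned, filtered by identity *within the
region*, and rescored; a term is projected onto an ortholog only when both
the global and the region alignments pass the NorMD reliability gate and
the ortholog survives both identity filters.

Eleven IDPO terms (IDPO:00024–IDPO:00034, mostly post-translational
modification display sites) depend on conservation of specific residues;
transfers of these are flagged ``tricky`` for expert review, never
suppressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

from .align import (
    AlignerSpec,
    CoordinateMap,
    align_family,
    drop_low_identity_rows,
    identity_to_reference,
)
from .io import AnnotatedEntry, AnnotatedRegion, Msa, ProteinRecord
from .prep import (
    cluster_by_identity,
    drop_singleton_clusters,
    filter_entries,
    filter_ortholog_lengths,
    load_provider_sets,
    merge_ortholog_sets,
)
from .quality import QualityReport, is_reliable, quality_report

logger = logging.getLogger(__name__)

TRICKY_TERMS = frozenset(f"IDPO:{n:05d}" for n in range(24, 35))


def flag_tricky_terms(term_id: str) -> bool:
    """True for the 11 residue-dependent IDPO terms; GO terms never tricky."""
    return term_id in TRICKY_TERMS


@dataclass
class TransferRecord:
    """One projected (ortholog, term, span) annotation with its evidence."""

    reference_accession: str
    region_id: str
    term_id: str
    term_name: str
    ref_start: int
    ref_end: int
    ortholog_accession: str
    ortho_start: int
    ortho_end: int
    region_normd: float
    region_identity: float
    n_orthologs_in_region: int
    tricky: bool

    def __post_init__(self) -> None:
        if self.ortho_start > self.ortho_end:
            raise ValueError("projected span reversed")


@dataclass
class PipelineConfig:
    """All pipeline knobs; the four identity thresholds form the study grid."""

    disprot_cluster_identity: float = 80.0
    aligner: AlignerSpec = field(default_factory=AlignerSpec)
    global_identity: float = 60.0
    region_identity: float = 60.0
    normd_min: float = 0.6
    length_filter_mode: Literal["literal", "strict"] = "literal"
    region_realign: bool = True
    region_gate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("disprot_cluster_identity", "global_identity", "region_identity"):
            value = getattr(self, name)
            if not (0 < value <= 100):
                raise ValueError(f"{name} must be in (0, 100], got {value}")


def parameter_grid(
    methods: Sequence[str] = ("clustal-omega", "mafft"),
    base: PipelineConfig | None = None,
) -> list[PipelineConfig]:
    """The 2×2×2×2 grid of clustering/aligner/global/region settings."""
    base = base or PipelineConfig()
    grid = []
    for cluster_id in (60.0, 80.0):
        for method in methods:
            for global_id in (60.0, 80.0):
                for region_id in (60.0, 80.0):
                    grid.append(
                        replace(
                            base,
                            disprot_cluster_identity=cluster_id,
                            aligner=AlignerSpec(method=method),  # type: ignore[arg-type]
                            global_identity=global_id,
                            region_identity=region_id,
                        )
                    )
    return grid


@dataclass
class RegionChop:
    """A region's column window in the global MSA plus per-row content."""

    columns: tuple[int, int]  # 1-based inclusive alignment columns
    sub_msa: Msa
    subsequences: dict[str, str]  # per present row, ungapped window content
    spans: dict[str, tuple[int, int]]  # per present row, own 1-based numbering
    absent: set[str]


def chop_region(msa: Msa, region: AnnotatedRegion) -> RegionChop:
    """Cut the column window spanned by a reference region out of the MSA.

    The window runs from the column of the region's first reference residue
    to the column of its last.  For every row the ungapped subsequence in
    that window and its span in the row's own 1-based numbering are
    returned; rows with no residues in the window are marked absent.
    """
    cmap = CoordinateMap(msa)
    n_ref = cmap.n_positions(msa.reference_id)
    if region.end > n_ref:
        raise ValueError(
            f"region {region.region_id} ({region.start}-{region.end}) outside "
            f"reference coverage ({n_ref} residues)"
        )
    c1 = cmap.seq_to_column(msa.reference_id, region.start)
    c2 = cmap.seq_to_column(msa.reference_id, region.end)
    sub = msa.slice_columns(c1, c2)
    subsequences: dict[str, str] = {}
    spans: dict[str, tuple[int, int]] = {}
    absent: set[str] = set()
    for row_id in msa.row_ids:
        ungapped = sub.ungapped(row_id)
        if not ungapped:
            absent.add(row_id)
            continue
        positions = [
            p
            for c in range(c1, c2 + 1)
            if (p := cmap.column_to_seq(row_id, c)) is not None
        ]
        subsequences[row_id] = ungapped
        spans[row_id] = (positions[0], positions[-1])
    return RegionChop(
        columns=(c1, c2),
        sub_msa=sub,
        subsequences=subsequences,
        spans=spans,
        absent=absent,
    )


@dataclass
class RegionResult:
    """Outcome of the per-region pipeline for one annotated region."""

    region: AnnotatedRegion
    chop: RegionChop | None
    region_msa: Msa | None
    report: QualityReport | None
    identities: dict[str, float]
    transferable: bool
    reason: str = ""


def _region_align(
    chop: RegionChop, row_ids: list[str], reference_id: str, config: PipelineConfig
) -> Msa:
    if config.region_realign:
        records = [
            ProteinRecord(accession=i, sequence=chop.subsequences[i])
            for i in row_ids
        ]
        return align_family(records, reference_id, config.aligner)
    return chop.sub_msa.select_rows(row_ids).drop_gap_only_columns()


def region_pipeline(
    msa: Msa, region: AnnotatedRegion, config: PipelineConfig
) -> RegionResult:
    """Chop → realign → region identity filter → realign survivors → NorMD.

    ``msa`` must already be the globally filtered family alignment.  Rows
    absent from the window never reappear.  Fewer than two surviving rows
    marks the region untransferable — that is data, not an error.  With the
    region gate disabled (the ungated comparison mode) the identity filter
    and reliability check are skipped and every present row survives.
    """
    chop = chop_region(msa, region)
    present = [i for i in msa.row_ids if i not in chop.absent]
    if msa.reference_id in chop.absent or len(present) < 2:
        return RegionResult(region, chop, None, None, {}, False,
                            "fewer than 2 rows in region window")
    aligned = _region_align(chop, present, msa.reference_id, config)
    identities = {
        i: identity_to_reference(aligned, i)
        for i in aligned.row_ids
        if i != msa.reference_id
    }
    if config.region_gate:
        survivors = [msa.reference_id] + [
            i for i in identities if identities[i] >= config.region_identity
        ]
    else:
        survivors = present
    if len(survivors) < 2:
        return RegionResult(region, chop, None, None, identities, False,
                            "fewer than 2 rows above region identity threshold")
    if set(survivors) != set(aligned.row_ids):
        aligned = _region_align(chop, [i for i in present if i in set(survivors)],
                                msa.reference_id, config)
    report = quality_report(aligned, scope="region", threshold=config.normd_min)
    transferable = report.reliable or not config.region_gate
    return RegionResult(
        region, chop, aligned, report,
        {i: identities[i] for i in identities if i in set(aligned.row_ids)},
        transferable,
        "" if transferable else "region NorMD below reliability threshold",
    )


def transfer_region(
    result: RegionResult,
    global_report: QualityReport,
    config: PipelineConfig,
    reference_accession: str,
) -> list[TransferRecord]:
    """Emit one record per surviving ortholog when both gates pass.

    A term travels only when the global *and* region alignments are
    reliable (NorMD strictly above ``normd_min``); a good global score with
    a bad region score, or the reverse, transfers nothing.  Projected spans
    are the first and last residues of the ortholog inside the region's
    column window, in the ortholog's own numbering.
    """
    if not is_reliable(global_report.normd, config.normd_min):
        return []
    if not result.transferable or result.region_msa is None:
        return []
    region = result.region
    orthologs = [
        i for i in result.region_msa.row_ids if i != result.region_msa.reference_id
    ]
    records = []
    for acc in orthologs:
        start, end = result.chop.spans[acc]
        records.append(
            TransferRecord(
                reference_accession=reference_accession,
                region_id=region.region_id,
                term_id=region.term_id,
                term_name=region.term_name,
                ref_start=region.start,
                ref_end=region.end,
                ortholog_accession=acc,
                ortho_start=start,
                ortho_end=end,
                region_normd=result.report.normd,
                region_identity=result.identities[acc],
                n_orthologs_in_region=len(orthologs),
                tricky=flag_tricky_terms(region.term_id),
            )
        )
    return records


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    records: list[TransferRecord]
    global_reports: dict[str, QualityReport]
    region_reports: dict[tuple[str, str], QualityReport]
    summary: dict[str, int]
    rejected_entries: list[tuple[str, str]] = field(default_factory=list)


def run_pipeline(
    entries: Sequence[AnnotatedEntry],
    ortholog_dir: str | Path,
    config: PipelineConfig | None = None,
    uniprot_sequences: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Run the full transfer pipeline over a set of annotated entries.

    Stages: entry filters → identity clustering of references → per-family
    ortholog merge and length filter → singleton removal → global alignment
    → global identity filter → global NorMD gate → per-region pipeline →
    transfer.  Failures in one family are logged and isolated; the run
    continues.  Stage counts are reported in ``summary``.
    """
    config = config or PipelineConfig()
    ortholog_dir = Path(ortholog_dir)
    summary = {
        "entries_total": len(entries),
        "entries_kept": 0,
        "clusters": 0,
        "families_with_orthologs": 0,
        "global_msas_built": 0,
        "global_msas_reliable": 0,
        "regions_processed": 0,
        "region_msas_reliable": 0,
        "terms_transferred": 0,
        "proteins_reached": 0,
    }
    kept, rejected = filter_entries(entries, uniprot_sequences)
    summary["entries_kept"] = len(kept)
    by_acc = {e.protein.accession: e for e in kept}
    clusters = cluster_by_identity(
        [e.protein for e in kept], config.disprot_cluster_identity
    )
    summary["clusters"] = len(clusters)

    with_orthologs = []
    for group in clusters:
        provider_sets = load_provider_sets(group.representative, ortholog_dir)
        if not provider_sets:
            continue
        merged = merge_ortholog_sets(provider_sets)
        ref_len = len(by_acc[group.representative].protein)
        kept_set, _dropped = filter_ortholog_lengths(
            merged, ref_len, config.length_filter_mode
        )
        with_orthologs.append((group, kept_set))
    families = drop_singleton_clusters(with_orthologs)
    summary["families_with_orthologs"] = len(families)

    all_records: list[TransferRecord] = []
    global_reports: dict[str, QualityReport] = {}
    region_reports: dict[tuple[str, str], QualityReport] = {}
    for group, oset in families:
        ref = group.representative
        entry = by_acc[ref]
        try:
            family_records = [entry.protein] + list(oset.orthologs)
            msa = align_family(family_records, ref, config.aligner)
            summary["global_msas_built"] += 1
            msa = drop_low_identity_rows(msa, config.global_identity)
            if msa.n_rows < 2:
                continue
            greport = quality_report(msa, scope="global", threshold=config.normd_min)
            global_reports[ref] = greport
            if not greport.reliable:
                continue
            summary["global_msas_reliable"] += 1
            for region in entry.regions:
                summary["regions_processed"] += 1
                result = region_pipeline(msa, region, config)
                if result.report is not None:
                    region_reports[(ref, region.region_id)] = result.report
                    if result.report.reliable:
                        summary["region_msas_reliable"] += 1
                all_records.extend(
                    transfer_region(result, greport, config, ref)
                )
        except Exception:
            logger.exception("family %s failed; continuing", ref)
    summary["terms_transferred"] = len(all_records)
    summary["proteins_reached"] = len({r.ortholog_accession for r in all_records})
    return PipelineResult(
        records=all_records,
        global_reports=global_reports,
        region_reports=region_reports,
        summary=summary,
        rejected_entries=[(e.protein.accession, rule) for e, rule in rejected],
    )
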