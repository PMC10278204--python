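"""Entry filters, redundancy clustering and ortholog-set preparation.

The annotated entries are first screened with four rules — canonical
accession, full-length sequence, no undefined residues, and agreement with
the supplied canonical sequence — then clustered greedily by pairwise
identity to remove redundancy.  Per-reference ortholog sets from multiple
providers are merged at the accession level and screened by length relative
to the reference before alignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

from .align import pairwise_identity
from .io import AnnotatedEntry, ProteinRecord, read_fasta

logger = logging.getLogger(__name__)

FilterRule = Literal[
    "not_canonical", "fragment", "undefined_residues", "sequence_mismatch"
]


@dataclass
class ClusterGroup:
    """One identity cluster: the founding (longest) member is representative."""

    representative: str
    members: list[str]
    identity_threshold: float

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a member")


@dataclass
class OrthologSet:
    """Merged orthologs of one reference, with per-accession provenance."""

    reference: str
    orthologs: list[ProteinRecord] = field(default_factory=list)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        accs = [r.accession for r in self.orthologs]
        if len(set(accs)) != len(accs):
            raise ValueError("duplicate ortholog accessions")
        if self.reference in accs:
            raise ValueError("reference listed among its own orthologs")


def filter_entries(
    entries: Sequence[AnnotatedEntry],
    uniprot_sequences: Mapping[str, str] | None = None,
    fragments: set[str] | None = None,
) -> tuple[list[AnnotatedEntry], list[tuple[AnnotatedEntry, FilterRule]]]:
    """Apply the four entry-screening rules; rejection is data, not an error.

    Rules, in order: (i) the accession is a canonical one (present in
    ``uniprot_sequences``); (ii) the entry is full-length (not listed in
    ``fragments``); (iii) the sequence has no undefined residues ('X');
    (iv) the sequence is identical to the canonical one.  Rules (i) and
    (iv) are skipped with a warning when no canonical map is supplied.
    Each rejection carries the first failing rule.
    """
    if uniprot_sequences is None:
        warnings.warn(
            "no canonical sequence map supplied; canonical-accession and "
            "sequence-identity rules skipped",
            stacklevel=2,
        )
    fragments = fragments or set()
    kept: list[AnnotatedEntry] = []
    rejected: list[tuple[AnnotatedEntry, FilterRule]] = []
    for entry in entries:
        acc = entry.protein.accession
        if uniprot_sequences is not None and acc not in uniprot_sequences:
            rejected.append((entry, "not_canonical"))
        elif acc in fragments:
            rejected.append((entry, "fragment"))
        elif entry.protein.has_undefined:
            rejected.append((entry, "undefined_residues"))
        elif (
            uniprot_sequences is not None
            and entry.protein.sequence != uniprot_sequences[acc].upper()
        ):
            rejected.append((entry, "sequence_mismatch"))
        else:
            kept.append(entry)
    return kept, rejected


def cluster_by_identity(
    records: Sequence[ProteinRecord], threshold: float
) -> list[ClusterGroup]:
    """Greedy incremental identity clustering (CD-HIT-like scheme).

    Sequences are visited longest first (ties broken by accession); each
    joins the first existing cluster whose representative it matches at
    ``threshold`` percent identity or better (identical pairs over full
    alignment length), else founds a new cluster.  The founding — hence
    longest — member is the representative.  The result is a partition of
    the input.
    """
    if not (0 < threshold <= 100):
        raise ValueError("threshold must be in (0, 100]")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.accession))
    clusters: list[ClusterGroup] = []
    by_acc = {r.accession: r for r in records}
    for rec in ordered:
        for group in clusters:
            rep_seq = by_acc[group.representative].sequence
            if pairwise_identity(rec.sequence, rep_seq) >= threshold:
                group.members.append(rec.accession)
                break
        else:
            clusters.append(
                ClusterGroup(
                    representative=rec.accession,
                    members=[rec.accession],
                    identity_threshold=threshold,
                )
            )
    return clusters


def merge_ortholog_sets(sets: Sequence[OrthologSet]) -> OrthologSet:
    """Accession-level union of ortholog sets sharing one reference.

    Provenance records every contributing provider.  When the same
    accession carries conflicting sequences the first one wins, with a
    warning.
    """
    if not sets:
        raise ValueError("nothing to merge")
    reference = sets[0].reference
    if any(s.reference != reference for s in sets):
        raise ValueError("ortholog sets do not share a reference")
    merged: dict[str, ProteinRecord] = {}
    provenance: dict[str, set[str]] = {}
    for oset in sets:
        for rec in oset.orthologs:
            providers = oset.provenance.get(rec.accession, set())
            if rec.accession in merged:
                if merged[rec.accession].sequence != rec.sequence:
                    warnings.warn(
                        f"conflicting sequences for {rec.accession}; keeping first",
                        stacklevel=2,
                    )
            else:
                merged[rec.accession] = rec
            provenance.setdefault(rec.accession, set()).update(providers)
    return OrthologSet(
        reference=reference,
        orthologs=list(merged.values()),
        provenance=provenance,
    )


def filter_ortholog_lengths(
    orthologs: OrthologSet,
    ref_length: int,
    mode: Literal["literal", "strict"] = "literal",
) -> tuple[OrthologSet, list[ProteinRecord]]:
    """Length screen relative to the reference, bounds inclusive.

    ``literal`` keeps lengths in [0.30, 1.30] × reference length (too-short
    sequences lack coverage, too-long ones likely carry extra domains);
    ``strict`` narrows the lower bound to 0.70.  Idempotent.
    """
    if ref_length <= 0:
        raise ValueError("ref_length must be positive")
    lo = {"literal": 0.30, "strict": 0.70}[mode] * ref_length
    hi = 1.30 * ref_length
    kept = [r for r in orthologs.orthologs if lo <= len(r.sequence) <= hi]
    rejected = [r for r in orthologs.orthologs if not lo <= len(r.sequence) <= hi]
    kept_set = OrthologSet(
        reference=orthologs.reference,
        orthologs=kept,
        provenance={
            r.accession: orthologs.provenance.get(r.accession, set()) for r in kept
        },
    )
    return kept_set, rejected


def drop_singleton_clusters(
    groups: Sequence[tuple[ClusterGroup, OrthologSet]]
) -> list[tuple[ClusterGroup, OrthologSet]]:
    """Remove families whose alignment would contain only the reference."""
    return [(g, o) for g, o in groups if len(o.orthologs) >= 1]


def load_provider_sets(
    reference: str, directory: str | Path
) -> list[OrthologSet]:
    """Read per-provider FASTA files ``<reference>.<provider>.fasta``."""
    directory = Path(directory)
    sets = []
    for path in sorted(directory.glob(f"{reference}.*.fasta")):
        provider = path.name[len(reference) + 1 : -len(".fasta")]
        records = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            parsed = read_fasta(path, source="ortholog")
        for rec in parsed:
            if rec.accession != reference:
                records.append(rec)
        sets.append(
            OrthologSet(
                reference=reference,
                orthologs=records,
                provenance={r.accession: {provider} for r in records},
            )
        )
    return sets
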