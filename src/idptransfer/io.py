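"""Readers and writers for every external representation the pipeline touches.

Formats handled here: DisProt-style JSON (annotated entries), plain and
aligned FASTA, Clustal alignments, the TSV transfer table and JSON quality
reports.  Coordinates in all external files are 1-based inclusive, the
DisProt convention; the single point of conversion to Python slices is
:meth:`AnnotatedRegion.slice`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

TRANSFER_TABLE_COLUMNS = [
    "reference_accession",
    "region_id",
    "term_id",
    "term_name",
    "ref_start",
    "ref_end",
    "ortholog_accession",
    "ortho_start",
    "ortho_end",
    "region_normd",
    "region_identity",
    "n_orthologs_in_region",
    "tricky",
]


class FormatError(ValueError):
    """Raised when an external file violates its format contract."""


@dataclass
class ProteinRecord:
    """A single protein sequence.

    ``source`` distinguishes annotated reference proteins from the orthologs
    they annotate.  Sequences are stored upper-case; the alphabet is the 20
    standard residues plus an optionally tolerated ``X`` (flagged via
    :attr:`has_undefined`, and rejected later by the entry filters).
    """

    accession: str
    sequence: str
    source: Literal["reference", "ortholog"] = "ortholog"
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES - {"X"}
        if bad:
            raise ValueError(
                f"{self.accession}: non-amino-acid characters {sorted(bad)}"
            )

    @property
    def has_undefined(self) -> bool:
        """True when the sequence contains undefined residues ('X')."""
        return "X" in self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotatedRegion:
    """One annotated span of a reference protein (1-based inclusive)."""

    region_id: str
    protein_accession: str
    start: int
    end: int
    term_id: str
    term_name: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.region_id}: invalid span {self.start}-{self.end}"
            )

    @property
    def ontology(self) -> str:
        """"GO" or "IDPO", derived from the term identifier prefix."""
        return self.term_id.split(":", 1)[0]

    @property
    def slice(self) -> slice:
        """0-based half-open slice — the only 1-based → 0-based conversion."""
        return slice(self.start - 1, self.end)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedEntry:
    """A reference protein together with its annotated regions."""

    protein: ProteinRecord
    regions: list[AnnotatedRegion] = field(default_factory=list)
    disprot_id: str = ""

    def __post_init__(self) -> None:
        for region in self.regions:
            if region.protein_accession != self.protein.accession:
                raise ValueError(
                    f"region {region.region_id} references "
                    f"{region.protein_accession}, not {self.protein.accession}"
                )

    def validate_bounds(self) -> list[str]:
        """Return one message per region whose span exceeds the sequence."""
        n = len(self.protein)
        return [
            f"region {r.region_id} span {r.start}-{r.end} exceeds sequence length {n}"
            for r in self.regions
            if r.end > n
        ]


@dataclass
class Msa:
    """A rectangular gapped alignment with one row marked as reference.

    Invariant (checked on construction): all rows have equal length and
    ungapping a row must recover the exact input sequence.  The gap
    character is normalised to ``-``.
    """

    row_ids: list[str]
    rows: list[str]
    reference_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows length mismatch")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row identifiers")
        self.rows = [r.upper().replace(".", GAP) for r in self.rows]
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            offender = max(self.row_ids, key=lambda i: len(self.row(i)))
            raise FormatError(f"ragged alignment: row {offender!r} has deviant length")
        if self.reference_id not in self.row_ids:
            raise ValueError(f"reference {self.reference_id!r} not among rows")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, row_id: str) -> str:
        return self.rows[self.row_ids.index(row_id)]

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    @property
    def reference_row(self) -> str:
        return self.row(self.reference_id)

    def select_rows(self, keep_ids: Sequence[str]) -> "Msa":
        """Sub-alignment restricted to ``keep_ids`` (original row order)."""
        keep = [i for i in self.row_ids if i in set(keep_ids)]
        return Msa(
            row_ids=keep,
            rows=[self.row(i) for i in keep],
            reference_id=self.reference_id,
            metadata=dict(self.metadata),
        )

    def slice_columns(self, start_col: int, end_col: int) -> "Msa":
        """Column window ``[start_col, end_col]``, 1-based inclusive."""
        if not (1 <= start_col <= end_col <= self.width):
            raise ValueError(f"column window {start_col}-{end_col} out of range")
        return Msa(
            row_ids=list(self.row_ids),
            rows=[r[start_col - 1 : end_col] for r in self.rows],
            reference_id=self.reference_id,
            metadata=dict(self.metadata),
        )

    def drop_gap_only_columns(self) -> "Msa":
        cols = [
            j for j in range(self.width)
            if any(row[j] != GAP for row in self.rows)
        ]
        return Msa(
            row_ids=list(self.row_ids),
            rows=["".join(r[j] for j in cols) for r in self.rows],
            reference_id=self.reference_id,
            metadata=dict(self.metadata),
        )


@dataclass
class DisProtParseResult:
    """Entries that parsed cleanly plus per-entry problems (never silent)."""

    entries: list[AnnotatedEntry]
    invalid: list[tuple[str, str]]  # (entry identifier, reason)


def _region_from_dict(raw: dict, accession: str, index: int) -> AnnotatedRegion:
    term = raw.get("term") or {}
    term_id = raw.get("term_id") or term.get("id") or ""
    term_name = raw.get("term_name") or term.get("name") or ""
    region_id = raw.get("region_id") or raw.get("id") or f"{accession}r{index:03d}"
    return AnnotatedRegion(
        region_id=region_id,
        protein_accession=accession,
        start=int(raw["start"]),
        end=int(raw["end"]),
        term_id=term_id,
        term_name=term_name,
    )


def read_disprot_json(path: str | Path) -> DisProtParseResult:
    """Parse a DisProt-style JSON release into annotated entries.

    Accepts either a top-level list of entries or the release layout with
    entries under a ``data`` key.  Per entry the fields used are ``acc``
    (or ``accession``), ``sequence``, ``disprot_id`` and ``regions`` with
    1-based inclusive ``start``/``end`` and a term (either a nested
    ``term`` object or flat ``term_id``/``term_name``).  Missing optional
    fields default to empty.  Entries that fail (bad sequence, region out
    of bounds) are reported in :attr:`DisProtParseResult.invalid`, never
    silently dropped.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: malformed JSON: {exc}") from exc
    raw_entries = payload.get("data", payload) if isinstance(payload, dict) else payload
    if not isinstance(raw_entries, list):
        raise FormatError(f"{path}: expected a list of entries")

    entries: list[AnnotatedEntry] = []
    invalid: list[tuple[str, str]] = []
    for i, raw in enumerate(raw_entries):
        ident = raw.get("disprot_id") or raw.get("acc") or f"entry#{i}"
        try:
            accession = raw.get("acc") or raw.get("accession")
            if not accession:
                raise ValueError("missing accession")
            protein = ProteinRecord(
                accession=accession,
                sequence=raw["sequence"],
                source="reference",
                description=raw.get("name", ""),
            )
            regions = [
                _region_from_dict(r, accession, j + 1)
                for j, r in enumerate(raw.get("regions", []))
            ]
            entry = AnnotatedEntry(
                protein=protein,
                regions=regions,
                disprot_id=raw.get("disprot_id", ""),
            )
        except (KeyError, ValueError, TypeError) as exc:
            invalid.append((ident, str(exc)))
            continue
        bounds = entry.validate_bounds()
        if bounds:
            invalid.append((ident, "; ".join(bounds)))
            continue
        entries.append(entry)
    for ident, reason in invalid:
        logger.warning("DisProt entry %s invalid: %s", ident, reason)
    return DisProtParseResult(entries=entries, invalid=invalid)


def read_fasta(path: str | Path, source: str = "ortholog") -> list[ProteinRecord]:
    """Read FASTA into protein records (order preserved, upper-cased)."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate accession {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                accession=rec.id,
                sequence=str(rec.seq),
                source=source,  # type: ignore[arg-type]
                description=rec.description[len(rec.id):].strip(),
            )
        )
    if not records:
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


MsaFormat = Literal["afa", "clustal"]


def read_msa(path: str | Path, format: MsaFormat = "afa", reference_id: str | None = None) -> Msa:
    """Read an aligned FASTA ("afa") or Clustal file into an :class:`Msa`.

    The reference row defaults to the first row when not named.  Ragged
    aligned-FASTA input raises :class:`FormatError` naming the offending
    row; both ``.`` and ``-`` are accepted as gaps on read.
    """
    path = Path(path)
    if format == "afa":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq))
    elif format == "clustal":
        try:
            aln = AlignIO.read(str(path), "clustal")
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        ids = [rec.id for rec in aln]
        rows = [str(rec.seq) for rec in aln]
    else:
        raise ValueError(f"unknown MSA format {format!r}")
    if not ids:
        raise FormatError(f"{path}: no alignment rows")
    return Msa(row_ids=ids, rows=rows, reference_id=reference_id or ids[0])


def write_msa(msa: Msa, path: str | Path, format: MsaFormat = "afa") -> None:
    records = [
        SeqRecord(Seq(row), id=row_id, description="")
        for row_id, row in zip(msa.row_ids, msa.rows)
    ]
    if format == "afa":
        SeqIO.write(records, str(path), "fasta")
    elif format == "clustal":
        AlignIO.write(MultipleSeqAlignment(records), str(path), "clustal")
    else:
        raise ValueError(f"unknown MSA format {format!r}")


def transfer_records_to_frame(records: Iterable) -> pd.DataFrame:
    """Transfer records as a DataFrame in the canonical column order/sort."""
    frame = pd.DataFrame(
        [
            {col: getattr(rec, col) for col in TRANSFER_TABLE_COLUMNS}
            for rec in records
        ],
        columns=TRANSFER_TABLE_COLUMNS,
    )
    return frame.sort_values(
        ["ref_start", "term_id", "ortholog_accession"], kind="mergesort"
    ).reset_index(drop=True)


def write_transfer_table(records: Iterable, path: str | Path) -> pd.DataFrame:
    """Write the TSV transfer table (header always present, deterministic sort)."""
    frame = transfer_records_to_frame(records)
    out = frame.copy()
    for col in ("region_normd",):
        out[col] = out[col].map(lambda v: f"{v:.4f}")
    for col in ("region_identity",):
        out[col] = out[col].map(lambda v: f"{v:.2f}")
    out.to_csv(path, sep="\t", index=False)
    return frame


def write_quality_report(report, path: str | Path) -> None:
    """Serialise a QualityReport (or mapping of them) to JSON."""
    from dataclasses import asdict, is_dataclass

    def conv(obj):
        if is_dataclass(obj):
            return asdict(obj)
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        return obj

    with open(path, "w") as fh:
        json.dump(conv(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
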