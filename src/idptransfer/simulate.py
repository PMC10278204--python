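"""Synthetic ortholog families with controlled identity and known truth.

The generator stands in for real ortholog databases: it derives each
ortholog from a random reference by an exact number of substitutions
(identity calibration is exact when no indels are planted) plus geometric-
length insertions and deletions, optionally with a different identity level
inside planted annotated windows (locally diverged decoys — the central
gating scenario).  Because every edit is recorded, the true alignment,
realized identities and projected spans are known by construction and
serve as ground truth for the whole pipeline.

Substituted residues are drawn with BLOSUM62-conditional weights
(``2^(score/2)``, identity excluded) rather than uniformly, so synthetic
families resemble real homolog families of the same percent identity in
the eyes of similarity-based quality scores.  Identity control, not
phylogenetic realism, is the goal: there is no rate matrix and no tree.

All randomness flows from one seed; each (family, ortholog) pair uses a
stable derived substream, so regeneration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .align import substitution_matrix
from .io import GAP, ProteinRecord, write_fasta

RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_N = len(RESIDUES)

# conditional substitution weights, diagonal zeroed
_SUB = substitution_matrix("BLOSUM62")[:_N, :_N]
_WEIGHTS = np.power(2.0, _SUB / 2.0)
np.fill_diagonal(_WEIGHTS, 0.0)
_WEIGHTS = _WEIGHTS / _WEIGHTS.sum(axis=1, keepdims=True)


@dataclass
class PlantedRegion:
    """An annotated window of the synthetic reference."""

    start: int  # 1-based inclusive
    end: int
    term_id: str
    term_name: str = ""
    identity_override: float | None = None  # percent, applies within window


@dataclass
class FamilySimConfig:
    """Generator settings for one synthetic ortholog family."""

    reference_length: int = 200
    n_orthologs: int = 10
    target_identities: Sequence[float] = ()  # one percent value per ortholog
    indel_rate: float = 0.02  # events per residue
    indel_length_mean: float = 2.0  # residues
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    indel_region_buffer: int = 2  # indel-free margin around planted windows
    seed: int = 0
    family_index: int = 0

    def __post_init__(self) -> None:
        if not self.target_identities:
            self.target_identities = [85.0] * self.n_orthologs
        if len(self.target_identities) != self.n_orthologs:
            raise ValueError("need one target identity per ortholog")
        for p in self.target_identities:
            if not (0 < p <= 100):
                raise ValueError("identities must be in (0, 100]")
        for region in self.planted_regions:
            if not (1 <= region.start <= region.end <= self.reference_length):
                raise ValueError(
                    f"planted region {region.start}-{region.end} outside reference"
                )
            if region.identity_override is not None:
                n_window = region.end - region.start + 1
                if n_window < 2:
                    raise ValueError("identity override needs a window of ≥2 residues")


@dataclass
class OrthologTruth:
    """Generation-time ground truth for one ortholog."""

    global_identity: float  # percent over reference positions
    region_identity: dict[str, float]  # term window → percent
    region_span: dict[str, tuple[int, int] | None]  # ortholog own numbering
    ref_row: str  # true alignment, reference row
    ortho_row: str  # true alignment, ortholog row


@dataclass
class SimulatedFamily:
    config: FamilySimConfig
    reference: ProteinRecord
    orthologs: list[ProteinRecord]
    truth: dict[str, OrthologTruth]
    accession: str = "REF000"


def _region_key(i: int, region: PlantedRegion) -> str:
    return f"r{i + 1:03d}"


def _sample_substitutions(rng, ref_codes, positions, n_sub):
    chosen = rng.choice(positions, size=n_sub, replace=False) if n_sub else []
    out = {}
    for pos in chosen:
        out[int(pos)] = int(rng.choice(_N, p=_WEIGHTS[ref_codes[pos]]))
    return out


def simulate_family(config: FamilySimConfig) -> SimulatedFamily:
    """Generate one family; deterministic given the config's seed."""
    L = config.reference_length
    root = np.random.default_rng(
        np.random.SeedSequence([config.seed, config.family_index])
    )
    ref_codes = root.integers(0, _N, size=L)
    ref_seq = "".join(RESIDUES[ref_codes])
    accession = f"REF{config.family_index:03d}"
    reference = ProteinRecord(accession, ref_seq, source="reference")

    override_pos: set[int] = set()
    for region in config.planted_regions:
        if region.identity_override is not None:
            override_pos.update(range(region.start - 1, region.end))
    forbidden_indel: set[int] = set()
    for region in config.planted_regions:
        lo = max(0, region.start - 1 - config.indel_region_buffer)
        hi = min(L, region.end + config.indel_region_buffer)
        forbidden_indel.update(range(lo, hi))
    free_pos = np.array(sorted(set(range(L)) - override_pos), dtype=int)
    indel_pool = np.array(sorted(set(range(L)) - forbidden_indel), dtype=int)

    orthologs: list[ProteinRecord] = []
    truth: dict[str, OrthologTruth] = {}
    for k, target in enumerate(config.target_identities):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, config.family_index, k])
        )
        subs: dict[int, int] = {}
        n_free = int(round((1 - target / 100.0) * free_pos.size))
        subs.update(_sample_substitutions(rng, ref_codes, free_pos, n_free))
        for region in config.planted_regions:
            if region.identity_override is None:
                continue
            window = np.arange(region.start - 1, region.end)
            n_win = int(round((1 - region.identity_override / 100.0) * window.size))
            subs.update(_sample_substitutions(rng, ref_codes, window, n_win))

        deleted = np.zeros(L, dtype=bool)
        insertions: dict[int, str] = {}  # residues inserted after ref position i
        if config.indel_rate > 0 and indel_pool.size > 0:
            n_events = rng.binomial(L, config.indel_rate)
            for _ in range(n_events):
                pos = int(rng.choice(indel_pool))
                length = int(rng.geometric(1.0 / config.indel_length_mean))
                if rng.random() < 0.5:  # deletion, clipped at forbidden zones
                    for d in range(length):
                        if pos + d >= L or (pos + d) in forbidden_indel:
                            break
                        deleted[pos + d] = True
                else:
                    ins = "".join(RESIDUES[rng.integers(0, _N, size=length)])
                    insertions[pos] = insertions.get(pos, "") + ins

        # true alignment rows
        ref_row_parts, ortho_row_parts = [], []
        ortho_pos_of_ref = np.zeros(L, dtype=int)  # 1-based, 0 where deleted
        counter = 0
        for i in range(L):
            ref_row_parts.append(ref_seq[i])
            if deleted[i]:
                ortho_row_parts.append(GAP)
            else:
                code = subs.get(i, int(ref_codes[i]))
                ortho_row_parts.append(RESIDUES[code])
                counter += 1
                ortho_pos_of_ref[i] = counter
            if i in insertions:
                ins = insertions[i]
                ref_row_parts.append(GAP * len(ins))
                ortho_row_parts.append(ins)
                counter += len(ins)
        ref_row = "".join(ref_row_parts)
        ortho_row = "".join(ortho_row_parts)
        ortho_seq = ortho_row.replace(GAP, "")

        matches = np.array(
            [
                (not deleted[i]) and (i not in subs)
                for i in range(L)
            ]
        )
        global_identity = 100.0 * matches.sum() / L
        region_identity: dict[str, float] = {}
        region_span: dict[str, tuple[int, int] | None] = {}
        for j, region in enumerate(config.planted_regions):
            window = slice(region.start - 1, region.end)
            w = np.arange(region.start - 1, region.end)
            region_identity[_region_key(j, region)] = (
                100.0 * matches[window].sum() / w.size
            )
            present = ortho_pos_of_ref[window][~deleted[window]]
            region_span[_region_key(j, region)] = (
                (int(present.min()), int(present.max())) if present.size else None
            )

        acc = f"{accession}_O{k:02d}"
        orthologs.append(ProteinRecord(acc, ortho_seq, source="ortholog"))
        truth[acc] = OrthologTruth(
            global_identity=global_identity,
            region_identity=region_identity,
            region_span=region_span,
            ref_row=ref_row,
            ortho_row=ortho_row,
        )
    return SimulatedFamily(
        config=config,
        reference=reference,
        orthologs=orthologs,
        truth=truth,
        accession=accession,
    )


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def make_disprot_fixture(
    families: Sequence[SimulatedFamily],
    out_dir: str | Path,
    providers: tuple[str, str] = ("oma", "orthoinspector"),
) -> Path:
    """Write a miniature annotated-entry JSON plus per-provider FASTA files.

    Orthologs are split between two providers with one shared accession so
    the provider merge is exercised; the fixture parses through the JSON
    reader and drives the full pipeline.  Returns the JSON path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for fam in families:
        disprot_id = f"DP9{fam.config.family_index:04d}"
        regions = [
            {
                "region_id": f"{disprot_id}{_region_key(j, region)}",
                "start": region.start,
                "end": region.end,
                "term": {"id": region.term_id, "name": region.term_name},
            }
            for j, region in enumerate(fam.config.planted_regions)
        ]
        entries.append(
            {
                "acc": fam.accession,
                "disprot_id": disprot_id,
                "sequence": fam.reference.sequence,
                "regions": regions,
            }
        )
        half = max(1, (len(fam.orthologs) + 1) // 2)
        first = fam.orthologs[:half]
        second = fam.orthologs[max(half - 1, 0):]  # one accession shared
        for provider, records in zip(providers, (first, second)):
            if records:
                write_fasta(records, out_dir / f"{fam.accession}.{provider}.fasta")
    json_path = out_dir / "entries.json"
    with open(json_path, "w") as fh:
        json.dump({"data": entries}, fh, indent=1)
        fh.write("\n")
    return json_path


def expected_transfers(
    families: Sequence[SimulatedFamily],
    global_identity: float,
    region_identity: float,
) -> pd.DataFrame:
    """Ground-truth expected transfer table for decoy-free configurations.

    An (ortholog, region) pair is expected iff the realized global identity
    and the realized within-region identity both clear their thresholds.
    The expectation assumes alignment quality gates pass, which holds when
    surviving identities sit above the reliability regime — the decoy-free
    benchmark is constructed that way.
    """
    rows = []
    for fam in families:
        disprot_id = f"DP9{fam.config.family_index:04d}"
        for j, region in enumerate(fam.config.planted_regions):
            key = _region_key(j, region)
            for ortho in fam.orthologs:
                t = fam.truth[ortho.accession]
                if t.global_identity < global_identity:
                    continue
                if t.region_identity[key] < region_identity:
                    continue
                span = t.region_span[key]
                if span is None:
                    continue
                rows.append(
                    {
                        "reference_accession": fam.accession,
                        "region_id": f"{disprot_id}{key}",
                        "term_id": region.term_id,
                        "ref_start": region.start,
                        "ref_end": region.end,
                        "ortholog_accession": ortho.accession,
                        "ortho_start": span[0],
                        "ortho_end": span[1],
                    }
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "reference_accession", "region_id", "term_id", "ref_start",
            "ref_end", "ortholog_accession", "ortho_start", "ortho_end",
        ],
    )
    return frame.sort_values(
        ["reference_accession", "ref_start", "term_id", "ortholog_accession"],
        kind="mergesort",
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# canned benchmark scenarios (the conditions every quality gate is tested under)
# ---------------------------------------------------------------------------

def benchmark_families(kind: str, seed: int) -> list[SimulatedFamily]:
    """Two standard scenarios used by tests and the acceptance script.

    ``clean``: three decoy-free families (8 orthologs each, length 200,
    identities 75–95%, sparse indels kept out of the two planted regions)
    where every planted (region, ortholog) pair should transfer.

    ``decoy``: the same families but each with one extra ortholog whose
    global identity stays high (~85%) while one planted window is diverged
    to ~30% identity — the locally unreliable case the region gate exists
    to catch.
    """
    if kind not in ("clean", "decoy"):
        raise ValueError(f"unknown benchmark kind {kind!r}")
    families = []
    for index in range(3):
        identities = [95.0, 92.0, 90.0, 88.0, 85.0, 82.0, 78.0, 75.0]
        regions = [
            PlantedRegion(31, 70, "IDPO:00076", "disorder"),
            PlantedRegion(121, 160, "GO:0005515", "protein binding"),
        ]
        if kind == "decoy":
            identities = identities + [85.0]
            regions = [
                PlantedRegion(31, 70, "IDPO:00076", "disorder"),
                PlantedRegion(121, 160, "GO:0005515", "protein binding"),
            ]
        config = FamilySimConfig(
            reference_length=200,
            n_orthologs=len(identities),
            target_identities=identities,
            indel_rate=0.01,
            indel_length_mean=2.0,
            planted_regions=regions,
            seed=seed,
            family_index=index,
        )
        fam = simulate_family(config)
        if kind == "decoy":
            fam = _diverge_last_ortholog(fam, region_index=0, identity=30.0)
        families.append(fam)
    return families


def _diverge_last_ortholog(
    fam: SimulatedFamily, region_index: int, identity: float
) -> SimulatedFamily:
    """Rebuild the family with the last ortholog locally diverged."""
    config = fam.config
    regions = [
        PlantedRegion(r.start, r.end, r.term_id, r.term_name,
                      identity if j == region_index else r.identity_override)
        for j, r in enumerate(config.planted_regions)
    ]
    decoy_config = FamilySimConfig(
        reference_length=config.reference_length,
        n_orthologs=config.n_orthologs,
        target_identities=list(config.target_identities),
        indel_rate=config.indel_rate,
        indel_length_mean=config.indel_length_mean,
        planted_regions=regions,
        indel_region_buffer=config.indel_region_buffer,
        seed=config.seed,
        family_index=config.family_index,
    )
    diverged = simulate_family(decoy_config)
    last = fam.orthologs[-1].accession
    orthologs = fam.orthologs[:-1] + [diverged.orthologs[-1]]
    truth = dict(fam.truth)
    truth[last] = diverged.truth[last]
    return SimulatedFamily(
        config=fam.config,
        reference=fam.reference,
        orthologs=orthologs,
        truth=truth,
        accession=fam.accession,
    )
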