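import shutil

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idptransfer.align import (
    AlignerNotFoundError,
    AlignerSpec,
    CoordinateMap,
    align_family,
    builtin_progressive_align,
    drop_low_identity_rows,
    identity_to_reference,
    pairwise_identity,
    substitution_matrix,
    encode,
)
from idptransfer.io import Msa, ProteinRecord

RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def random_records(rng, n, length, base=None, n_sub=0):
    records = []
    for i in range(n):
        if base is None:
            seq = "".join(rng.choice(RESIDUES, length))
        else:
            chars = list(base)
            for pos in rng.choice(len(base), size=n_sub, replace=False):
                chars[pos] = rng.choice([c for c in RESIDUES if c != chars[pos]])
            seq = "".join(chars)
        records.append(ProteinRecord(f"s{i}", seq))
    return records


class TestBuiltinAligner:
    def test_identical_pair_aligns_gap_free(self):
        records = [ProteinRecord("a", "ACDEFGHIKL"), ProteinRecord("b", "ACDEFGHIKL")]
        msa = align_family(records, "a")
        assert msa.rows == ["ACDEFGHIKL", "ACDEFGHIKL"]

    def test_three_identical_sequences_gap_free(self):
        records = [ProteinRecord(c, "ACDEFGHIKLMNP") for c in "abc"]
        msa = builtin_progressive_align(records, "a")
        assert all(row == "ACDEFGHIKLMNP" for row in msa.rows)

    def test_deletion_produces_single_gap_column(self):
        msa = align_family([ProteinRecord("a", "ACDE"), ProteinRecord("b", "ACE")], "a")
        assert msa.row("a") == "ACDE"
        assert msa.row("b").count("-") == 1
        assert msa.ungapped("b") == "ACE"

    def test_pairwise_case_matches_biopython_dp_score(self):
        # n=2 reduces to plain global affine-gap alignment; scores must agree
        from Bio import Align
        from Bio.Align import substitution_matrices

        rng = np.random.default_rng(12)
        sub = substitution_matrix()
        for _ in range(5):
            a, b = random_records(rng, 2, 40)
            msa = builtin_progressive_align([a, b], "s0")
            ra, rb = encode_row(msa.row("s0")), encode_row(msa.row("s1"))
            my_score = score_alignment(ra, rb, sub, 10.0, 0.5)
            aligner = Align.PairwiseAligner()
            aligner.mode = "global"
            aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
            aligner.open_gap_score = -10.0
            aligner.extend_gap_score = -0.5
            assert my_score == pytest.approx(aligner.score(a.sequence, b.sequence))

    def test_sum_of_pairs_beats_star_alignment_oracle(self):
        # a trivial star alignment to the reference is a lower bound on quality
        rng = np.random.default_rng(21)
        sub = substitution_matrix()
        for trial in range(3):
            base = "".join(rng.choice(RESIDUES, 60))
            records = random_records(rng, 5, 60, base=base, n_sub=8)
            msa = builtin_progressive_align(records, "s0")
            rows = [encode_row(msa.row(i)) for i in msa.row_ids]
            sp = sum(
                score_alignment(rows[i], rows[k], sub, 10.0, 0.5)
                for i in range(5) for k in range(i + 1, 5)
            )
            # star: sequences are equal-length point mutants, so the ungapped
            # stack is itself a valid alignment — score it directly
            star_rows = [encode_row(r.sequence) for r in records]
            star = sum(
                score_alignment(star_rows[i], star_rows[k], sub, 10.0, 0.5)
                for i in range(5) for k in range(i + 1, 5)
            )
            assert sp >= star - 1e-9

    def test_ungap_recovers_inputs_for_random_families(self):
        rng = np.random.default_rng(33)
        base = "".join(rng.choice(RESIDUES, 70))
        records = random_records(rng, 6, 70, base=base, n_sub=12)
        # introduce length variation
        records[3] = ProteinRecord("s3", records[3].sequence[:60])
        msa = builtin_progressive_align(records, "s0")
        for rec in records:
            assert msa.ungapped(rec.accession) == rec.sequence

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            align_family([ProteinRecord("a", "ACDE")], "a")

    def test_unknown_reference_rejected(self):
        records = [ProteinRecord("a", "ACDE"), ProteinRecord("b", "ACDE")]
        with pytest.raises(ValueError, match="reference"):
            align_family(records, "zz")


def encode_row(row):
    return np.array([-1 if c == "-" else int(encode(c)[0]) for c in row])


def score_alignment(a, b, sub, gap_open, gap_extend):
    """Independent sum-of-pairs scorer for two gapped rows (affine gaps)."""
    score, in_gap = 0.0, False
    for x, y in zip(a, b):
        if x >= 0 and y >= 0:
            score += sub[x, y]
            in_gap = False
        elif x < 0 and y < 0:
            continue
        else:
            score -= gap_extend if in_gap else gap_open
            in_gap = True
    return score


@pytest.mark.skipif(shutil.which("mafft") is None, reason="mafft not installed")
class TestMafftAdapter:
    def test_mafft_alignment_recovers_sequences(self):
        rng = np.random.default_rng(8)
        base = "".join(rng.choice(RESIDUES, 80))
        records = random_records(rng, 4, 80, base=base, n_sub=10)
        msa = align_family(records, "s0", AlignerSpec(method="mafft"))
        assert msa.metadata["method"] == "mafft"
        for rec in records:
            assert msa.ungapped(rec.accession) == rec.sequence

    def test_external_and_builtin_clear_pairwise_identity_floor(self):
        rng = np.random.default_rng(44)
        base = "".join(rng.choice(RESIDUES, 90))
        records = random_records(rng, 5, 90, base=base, n_sub=9)  # ~90% identity
        floor = min(
            pairwise_identity(records[0].sequence, r.sequence) for r in records[1:]
        )
        for method in ("builtin", "mafft"):
            msa = align_family(records, "s0", AlignerSpec(method=method))
            for rec in records[1:]:
                assert identity_to_reference(msa, rec.accession) >= floor - 1e-9


def test_missing_external_binary_raises_helpful_error(monkeypatch):
    monkeypatch.setattr(shutil, "which", lambda name: None)
    records = [ProteinRecord("a", "ACDE"), ProteinRecord("b", "ACDE")]
    with pytest.raises(AlignerNotFoundError, match="builtin"):
        align_family(records, "a", AlignerSpec(method="clustal-omega"))


class TestIdentityToReference:
    def test_identical_rows_score_100(self):
        msa = Msa(["r", "o"], ["ACDE", "ACDE"], "r")
        assert identity_to_reference(msa, "o") == 100.0

    def test_gap_opposite_reference_residue_is_mismatch(self):
        msa = Msa(["r", "o"], ["ACDE", "A-DE"], "r")
        assert identity_to_reference(msa, "o") == 75.0

    def test_matches_brute_force_column_scan(self):
        rng = np.random.default_rng(15)
        chars = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
        for _ in range(10):
            ref = "".join(rng.choice(chars, 50))
            other = "".join(rng.choice(chars, 50))
            if ref.strip("-") == "":
                continue
            msa = Msa(["r", "o"], [ref, other], "r")
            matches = denom = 0
            for a, b in zip(ref, other):
                if a != "-":
                    denom += 1
                    matches += a == b
            assert identity_to_reference(msa, "o") == pytest.approx(
                100.0 * matches / denom
            )

    def test_invariant_to_row_order_and_gap_only_columns(self):
        msa = Msa(["r", "o", "p"], ["AC-DE", "ACDDE", "A--DE"], "r")
        base = identity_to_reference(msa, "o")
        shuffled = Msa(["p", "o", "r"], ["A--DE", "ACDDE", "AC-DE"], "r")
        assert identity_to_reference(shuffled, "o") == base
        padded = Msa(["r", "o", "p"], ["AC--DE", "ACD-DE", "A---DE"], "r")
        assert identity_to_reference(padded, "o") == base

    def test_reference_all_gap_in_range_is_an_error(self):
        msa = Msa(["r", "o"], ["--AC", "GGAC"], "r")
        with pytest.raises(ValueError, match="all-gap"):
            identity_to_reference(msa, "o", columns=(1, 2))


class TestDropLowIdentityRows:
    def test_identical_rows_all_retained(self):
        msa = Msa(["r", "a", "b"], ["ACDE"] * 3, "r")
        assert drop_low_identity_rows(msa, 80).n_rows == 3

    def test_decoy_below_threshold_removed_reference_kept(self):
        msa = Msa(["r", "good", "decoy"], ["ACDEFGHI", "ACDEFGHL", "AGGGGGHI"], "r")
        filtered = drop_low_identity_rows(msa, 60)
        assert filtered.row_ids == ["r", "good"]

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(19)
        base = "".join(rng.choice(RESIDUES, 50))
        rows = [base]
        for i in range(6):
            chars = list(base)
            for pos in rng.choice(50, size=6 * i, replace=False):
                chars[pos] = rng.choice([c for c in RESIDUES if c != chars[pos]])
            rows.append("".join(chars))
        msa = Msa([f"s{i}" for i in range(7)], rows, "s0")
        at60 = drop_low_identity_rows(msa, 60)
        again = drop_low_identity_rows(at60, 60)
        assert again.row_ids == at60.row_ids
        at80 = drop_low_identity_rows(msa, 80)
        assert set(at80.row_ids) <= set(at60.row_ids)


class TestCoordinateMap:
    def test_position_through_gap(self):
        msa = Msa(["a", "b"], ["A-CD", "AACD"], "a")
        cmap = CoordinateMap(msa)
        assert cmap.seq_to_column("a", 2) == 3
        assert cmap.column_to_seq("a", 2) is None
        assert cmap.column_to_seq("a", 3) == 2

    def test_out_of_range_raises(self):
        cmap = CoordinateMap(Msa(["a"], ["A-CD"], "a"))
        with pytest.raises(IndexError):
            cmap.seq_to_column("a", 4)
        with pytest.raises(IndexError):
            cmap.column_to_seq("a", 5)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from("ACDG-"), min_size=1, max_size=60))
    def test_roundtrip_identity_on_random_gapped_rows(self, chars):
        row = "".join(chars)
        if row.strip("-") == "":
            row = row + "A"
        msa = Msa(["a"], [row], "a")
        cmap = CoordinateMap(msa)
        n = cmap.n_positions("a")
        for pos in range(1, n + 1):
            assert cmap.column_to_seq("a", cmap.seq_to_column("a", pos)) == pos
        for col in range(1, len(row) + 1):
            pos = cmap.column_to_seq("a", col)
            if pos is not None:
                assert cmap.seq_to_column("a", pos) == col
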