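from dataclasses import replace

import numpy as np
import pytest

from idptransfer.align import align_family
from idptransfer.io import AnnotatedRegion, Msa, ProteinRecord, transfer_records_to_frame
from idptransfer.quality import QualityReport
from idptransfer.simulate import (
    FamilySimConfig,
    PlantedRegion,
    expected_transfers,
    simulate_family,
)
from idptransfer.transfer import (
    PipelineConfig,
    chop_region,
    flag_tricky_terms,
    parameter_grid,
    region_pipeline,
    run_pipeline,
    transfer_region,
)


def region(start, end, term="IDPO:00076", acc="r", rid="reg1"):
    return AnnotatedRegion(rid, acc, start, end, term)


class TestTrickyTerms:
    @pytest.mark.parametrize("n", range(24, 35))
    def test_all_eleven_residue_dependent_idpo_terms_flagged(self, n):
        assert flag_tricky_terms(f"IDPO:{n:05d}") is True

    @pytest.mark.parametrize(
        "term", ["IDPO:00076", "IDPO:00023", "IDPO:00035", "GO:0005515", "GO:0140693"]
    )
    def test_other_terms_never_flagged(self, term):
        assert flag_tricky_terms(term) is False


class TestChopRegion:
    def test_gap_free_alignment_maps_directly(self):
        msa = Msa(["r", "o"], ["ACDEF", "ACDEF"], "r")
        chop = chop_region(msa, region(2, 4))
        assert chop.columns == (2, 4)
        assert chop.subsequences == {"r": "CDE", "o": "CDE"}
        assert chop.spans["o"] == (2, 4)

    def test_window_maps_through_reference_gap(self):
        msa = Msa(["r", "o"], ["A-CD", "AACD"], "r")
        chop = chop_region(msa, region(2, 3))
        assert chop.columns == (3, 4)
        assert chop.subsequences["r"] == "CD"
        assert chop.spans["o"] == (3, 4)

    def test_row_with_no_residues_in_window_marked_absent(self):
        msa = Msa(["r", "o"], ["ACDEF", "A---F"], "r")
        chop = chop_region(msa, region(2, 4))
        assert chop.absent == {"o"}

    def test_region_outside_reference_coverage_raises(self):
        msa = Msa(["r", "o"], ["ACD", "ACD"], "r")
        with pytest.raises(ValueError, match="outside reference"):
            chop_region(msa, region(2, 9))

    def test_simulated_indels_match_coordinate_oracle(self):
        config = FamilySimConfig(
            reference_length=120, n_orthologs=4,
            target_identities=[90.0] * 4, indel_rate=0.05,
            planted_regions=[PlantedRegion(41, 70, "IDPO:00076")], seed=3,
        )
        fam = simulate_family(config)
        # use the generation-time true alignment as the MSA
        row_ids = [fam.accession] + [o.accession for o in fam.orthologs]
        for ortho in fam.orthologs:
            truth = fam.truth[ortho.accession]
            msa = Msa([fam.accession, ortho.accession],
                      [truth.ref_row, truth.ortho_row], fam.accession)
            chop = chop_region(msa, region(41, 70, acc=fam.accession))
            span = truth.region_span["r001"]
            assert chop.spans[ortho.accession] == span
            # the subsequence is exactly the ortholog's substring over the span
            assert chop.subsequences[ortho.accession] == ortho.sequence[
                span[0] - 1 : span[1]
            ]


def family_msa_with_decoy(seed=17):
    """Reference + 3 good orthologs + 1 decoy diverged only in 41..80."""
    config = FamilySimConfig(
        reference_length=160, n_orthologs=4,
        target_identities=[95.0, 92.0, 90.0, 95.0],
        indel_rate=0.0,
        planted_regions=[PlantedRegion(41, 80, "IDPO:00076",
                                       identity_override=None)],
        seed=seed,
    )
    decoy_config = replace(
        config,
        planted_regions=[PlantedRegion(41, 80, "IDPO:00076",
                                       identity_override=30.0)],
    )
    fam = simulate_family(config)
    diverged = simulate_family(decoy_config)
    decoy = diverged.orthologs[-1]
    records = [fam.reference] + fam.orthologs[:-1] + [decoy]
    msa = align_family(records, fam.accession)
    return fam, decoy, msa


class TestRegionPipeline:
    def test_identical_orthologs_keep_all_rows_and_pass(self):
        msa = Msa(["r", "a", "b"], ["ACDEFGHIKLMNPQRSTVWY"] * 3, "r")
        result = region_pipeline(msa, region(5, 15), PipelineConfig())
        assert result.transferable
        assert result.region_msa.n_rows == 3
        assert result.report.reliable

    def test_locally_diverged_decoy_dropped_from_region_kept_globally(self):
        fam, decoy, msa = family_msa_with_decoy()
        from idptransfer.align import drop_low_identity_rows, identity_to_reference

        filtered = drop_low_identity_rows(msa, 60)
        assert decoy.accession in filtered.row_ids  # survives the global gate
        result = region_pipeline(
            filtered, region(41, 80, acc=fam.accession), PipelineConfig()
        )
        assert result.transferable
        assert decoy.accession not in result.region_msa.row_ids
        survivors = set(result.region_msa.row_ids) - {fam.accession}
        assert survivors == {o.accession for o in fam.orthologs[:-1]}

    def test_fewer_than_two_survivors_is_untransferable_data(self):
        msa = Msa(["r", "o"], ["ACDEFGHIKL", "GGGGGGGGGG"], "r")
        result = region_pipeline(msa, region(1, 10), PipelineConfig())
        assert not result.transferable
        assert "threshold" in result.reason


class TestTransferRegion:
    def test_unreliable_global_alignment_transfers_nothing(self):
        msa = Msa(["r", "a", "b"], ["ACDEFGHIKL"] * 3, "r")
        result = region_pipeline(msa, region(2, 9), PipelineConfig())
        bad_global = QualityReport(normd=0.3, n_rows=3, n_columns=10,
                                   scope="global", reliable=False)
        assert transfer_region(result, bad_global, PipelineConfig(), "r") == []

    def test_reliable_global_but_unreliable_region_transfers_nothing(self):
        rng = np.random.default_rng(2)
        residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        head = "".join(rng.choice(residues, 30))
        rows = [head + "".join(rng.choice(residues, 30)) for _ in range(3)]
        msa = Msa(["r", "a", "b"], rows, "r")
        config = PipelineConfig(region_identity=1e-9)  # isolate the NorMD gate
        result = region_pipeline(msa, region(31, 60), config)
        assert result.report is not None and not result.report.reliable
        good_global = QualityReport(normd=0.9, n_rows=3, n_columns=60,
                                    scope="global", reliable=True)
        assert transfer_region(result, good_global, config, "r") == []

    def test_clean_family_emits_one_record_per_ortholog(self):
        config = FamilySimConfig(
            reference_length=100, n_orthologs=10,
            target_identities=[90.0] * 10, indel_rate=0.0,
            planted_regions=[PlantedRegion(21, 60, "IDPO:00025", "acetylation")],
            seed=5,
        )
        fam = simulate_family(config)
        msa = align_family([fam.reference] + fam.orthologs, fam.accession)
        pipeline_config = PipelineConfig()
        result = region_pipeline(
            msa, region(21, 60, term="IDPO:00025", acc=fam.accession), pipeline_config
        )
        from idptransfer.quality import quality_report

        records = transfer_region(
            result, quality_report(msa), pipeline_config, fam.accession
        )
        assert len(records) == 10
        for rec in records:
            assert rec.tricky is True  # IDPO:00025 is a residue-dependent term
            assert (rec.ortho_start, rec.ortho_end) == (21, 60)  # no indels planted
            assert rec.n_orthologs_in_region == 10


class TestRunPipeline:
    def test_empty_ortholog_directory_transfers_nothing(self, tmp_path, clean_entries):
        result = run_pipeline(clean_entries, tmp_path, PipelineConfig())
        assert result.summary["terms_transferred"] == 0
        assert result.summary["families_with_orthologs"] == 0
        assert result.summary["clusters"] > 0

    def test_transfer_table_matches_generator_ground_truth(
        self, clean_families, clean_entries, clean_fixture_dir
    ):
        config = PipelineConfig()
        result = run_pipeline(clean_entries, clean_fixture_dir, config)
        got = transfer_records_to_frame(result.records)
        expected = expected_transfers(
            clean_families, config.global_identity, config.region_identity
        )
        got = got[list(expected.columns)].sort_values(
            list(expected.columns), kind="mergesort"
        ).reset_index(drop=True)
        expected = expected.sort_values(
            list(expected.columns), kind="mergesort"
        ).reset_index(drop=True)
        assert got.astype(str).equals(expected.astype(str))

    def test_gate_soundness_no_record_violates_thresholds(
        self, decoy_entries, decoy_fixture_dir
    ):
        config = PipelineConfig()
        result = run_pipeline(decoy_entries, decoy_fixture_dir, config)
        assert result.records
        for rec in result.records:
            assert rec.region_normd > config.normd_min
            assert rec.region_identity >= config.region_identity

    def test_table_row_count_equals_reported_transfer_count(
        self, clean_entries, clean_fixture_dir, tmp_path
    ):
        from idptransfer.io import write_transfer_table

        result = run_pipeline(clean_entries, clean_fixture_dir, PipelineConfig())
        path = tmp_path / "t.tsv"
        write_transfer_table(result.records, path)
        n_lines = len(path.read_text().splitlines())
        assert n_lines - 1 == result.summary["terms_transferred"]


class TestConfig:
    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            PipelineConfig(global_identity=0)
        with pytest.raises(ValueError):
            PipelineConfig(region_identity=101)

    def test_parameter_grid_covers_sixteen_combinations(self):
        grid = parameter_grid()
        assert len(grid) == 16
        combos = {
            (c.disprot_cluster_identity, c.aligner.method,
             c.global_identity, c.region_identity)
            for c in grid
        }
        assert len(combos) == 16
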