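import json

import pytest
from click.testing import CliRunner

from qcakit import (
    MembershipAssignmentError,
    OutcomeClass,
    RunConfig,
    analyse,
    run_analysis,
    sensitivity_recalibrate,
)
from qcakit.cli import main


class TestAnalyse:
    def test_model1_positive_rows_under_published_memberships(self, breastfeeding, model1):
        # the published analysis reported a single passing row, but that
        # rested on revised outcome memberships (see fixtures.ERRATA); from
        # the published data table (0,0,0) also clears the 0.75 cutoff
        result = analyse(breastfeeding, model1)
        assert set(result.truth_table.positive_corners) == {(0, 1, 1), (0, 0, 0)}

    def test_negated_model_has_single_positive_row(self, breastfeeding, model1):
        result = analyse(breastfeeding, model1, negate_outcome=True)
        assert result.truth_table.positive_corners == ((0, 1, 0),)
        assert result.solution_label == "~Empowerment*Design*~Lay-led"

    def test_model3_solution_is_intensity(self, breastfeeding, model3):
        result = analyse(breastfeeding, model3)
        assert set(result.truth_table.positive_corners) == {(1, 0), (1, 1)}
        assert result.solution_label == "Intensity"
        assert result.metrics.solution_coverage == pytest.approx(0.560, abs=5e-4)

    def test_no_positive_rows_yields_no_solution(self, breastfeeding):
        # a single engagement condition cannot separate the outcomes: both
        # rows are contradictory, so nothing passes to minimisation
        result = analyse(breastfeeding, ("Empowerment",))
        assert result.solution is None
        assert result.metrics is None


class TestRunAnalysis:
    def test_report_bundle_files(self, breastfeeding, tmp_path):
        config = RunConfig(conditions=("Intensity", "Quality"), out_dir=tmp_path / "out")
        result = run_analysis(config, table=breastfeeding)
        for name in ("data_table.csv", "truth_table.csv", "report.txt", "report.json"):
            assert (tmp_path / "out" / name).exists()
        doc = json.loads((tmp_path / "out" / "report.json").read_text())
        assert doc["schema_version"] == 1
        assert doc["solution"]["expression"] == result.solution_label
        assert doc["solution"]["coverage"] == 0.560

    def test_repeated_runs_are_byte_identical(self, breastfeeding, tmp_path):
        for d in ("a", "b"):
            run_analysis(
                RunConfig(conditions=("Intensity", "Quality"), out_dir=tmp_path / d),
                table=breastfeeding,
            )
        assert (tmp_path / "a" / "report.json").read_bytes() == (
            tmp_path / "b" / "report.json"
        ).read_bytes()

    def test_text_report_numbers_appear_in_json(self, breastfeeding, tmp_path):
        config = RunConfig(conditions=("Intensity", "Quality"), out_dir=tmp_path / "out")
        result = run_analysis(config, table=breastfeeding)
        doc = json.loads((tmp_path / "out" / "report.json").read_text())
        text = (tmp_path / "out" / "report.txt").read_text()
        assert str(doc["solution"]["coverage"]) in text
        assert str(doc["solution"]["consistency"]) in text
        for row in doc["truth_table"]["rows"]:
            if row["raw_consistency"] is not None:
                assert f"{row['raw_consistency']:.3f}" in text


class TestSensitivity:
    def test_identity_perturbation_changes_nothing(self, breastfeeding, model3):
        config = RunConfig(conditions=model3, strategy="vote_count")
        result = sensitivity_recalibrate(config, "Pugh (2002)", 0.666, table=breastfeeding)
        assert not result.solution_changed
        assert all(d in (None, 0.0) for d in result.consistency_deltas().values())
        assert result.base.metrics.solution_coverage == result.altered.metrics.solution_coverage

    def test_pugh_recalibration_weakens_but_keeps_the_solution(self, breastfeeding, model3):
        config = RunConfig(conditions=model3, strategy="vote_count")
        result = sensitivity_recalibrate(config, "Pugh (2002)", 0.333, table=breastfeeding)
        assert not result.solution_changed
        assert (
            result.altered.metrics.solution_coverage < result.base.metrics.solution_coverage
        )
        assert (
            result.altered.metrics.solution_consistency
            < result.base.metrics.solution_consistency
        )
        # the perturbed row becomes genuinely mixed; vote-count keeps it
        row = result.altered.truth_table.row((1, 1))
        assert row.outcome_class is OutcomeClass.POSITIVE
        assert "vote 3:1" in row.note

    def test_crossover_outcome_surfaces_assignment_error(self, breastfeeding, model3):
        config = RunConfig(conditions=model3)
        with pytest.raises(MembershipAssignmentError):
            sensitivity_recalibrate(config, "Pugh (2002)", 0.5, table=breastfeeding)

    def test_unknown_case_rejected(self, breastfeeding, model3):
        with pytest.raises(Exception, match="unknown case"):
            sensitivity_recalibrate(
                RunConfig(conditions=model3), "Nobody (1999)", 0.4, table=breastfeeding
            )


class TestCli:
    def test_run_fixture_model3(self):
        runner = CliRunner()
        result = runner.invoke(main, ["run", "--fixture", "--conditions", "Intensity,Quality"])
        assert result.exit_code == 0, result.output
        assert "Solution (conservative): Intensity" in result.output

    def test_run_exit_code_distinguishes_no_solution(self):
        runner = CliRunner()
        result = runner.invoke(main, ["run", "--fixture", "--conditions", "Empowerment"])
        assert result.exit_code == 3

    def test_sensitivity_command(self):
        runner = CliRunner()
        result = runner.invoke(
            main,
            [
                "sensitivity", "--fixture", "--conditions", "Intensity,Quality",
                "--strategy", "vote", "--case", "Pugh (2002)", "--set-outcome", "0.333",
            ],
        )
        assert result.exit_code == 0, result.output
        assert "solution (altered): Intensity" in result.output

    def test_generate_command(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "synthetic.csv"
        result = runner.invoke(
            main,
            ["generate", "--k", "3", "--n", "10", "--dnf", "A + B*~C", "--seed", "4",
             "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert out.exists()
        assert out.read_text().count("\n") == 11  # header + 10 cases

    def test_run_with_data_file_and_yaml_schema(self, tmp_path):
        (tmp_path / "data.csv").write_text(
            "case_id,A,B,y\n"
            "s1,1,0,1\ns2,1,1,1\ns3,0,1,1\ns4,0,0,0\n"
        )
        (tmp_path / "schema.yaml").write_text(
            "case_id: case_id\n"
            "conditions:\n  - {name: A, kind: crisp}\n  - {name: B, kind: crisp}\n"
            "outcome: {name: y, calibrated: true}\n"
        )
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["run", "--data", str(tmp_path / "data.csv"),
             "--schema", str(tmp_path / "schema.yaml"),
             "--out", str(tmp_path / "out")],
        )
        assert result.exit_code == 0, result.output
        assert "Solution (conservative): A + B" in result.output
        assert (tmp_path / "out" / "report.json").exists()

    def test_run_requires_data_or_fixture(self):
        runner = CliRunner()
        result = runner.invoke(main, ["run", "--conditions", "A"])
        assert result.exit_code != 0
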