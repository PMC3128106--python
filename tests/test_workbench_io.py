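"""Fixture loading, TSV round trips, scenario config, report, and CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from lipidgen import workbench_io as w
from lipidgen.cli import main as cli_main
from lipidgen.errors import SchemaError
from lipidgen.phenotypes import HDL


class TestFixtureLoading:
    def test_panel_shape(self, fixture_set):
        assert {t: df["snp"].nunique() for t, df in fixture_set.tables.items()} == {
            "HDL-C": 27,
            "LDL-C": 19,
            "lnTG": 14,
        }
        for df in fixture_set.tables.values():
            assert set(df["population"]) == {"EA", "AA", "AI", "MAH"}
            assert set(df["generalized"]) <= {"Y", "N"}
            caf = df["caf"].dropna()
            assert ((caf >= 0) & (caf <= 1)).all()

    def test_scientific_notation_parsed(self, fixture_set):
        hdl = fixture_set.tables["HDL-C"]
        row = hdl[(hdl["snp"] == "rs3764261") & (hdl["population"] == "EA")].iloc[0]
        assert row["p"] == pytest.approx(8.83e-129)
        assert row["p_text"] == "8.83E-129"

    def test_missing_cells_are_nan(self, fixture_set):
        hdl = fixture_set.tables["HDL-C"]
        row = hdl[(hdl["snp"] == "rs4149268") & (hdl["population"] == "AI")].iloc[0]
        assert np.isnan(row["p"]) and np.isnan(row["beta"])

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("snp\tcoded_allele\tgeneralized\n")
        with pytest.raises(SchemaError):
            w.load_summary_table(path, HDL)

    def test_malformed_p_rejected(self, tmp_path, fixture_set):
        src = pd.read_csv(
            w.resources.files("lipidgen") / "data" / "hdl_summary.tsv", sep="\t", dtype=str
        )
        src.loc[0, "EA_p"] = "not-a-number"
        path = tmp_path / "bad.tsv"
        src.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="malformed"):
            w.load_summary_table(path, HDL)

    def test_duplicate_snp_rejected(self, tmp_path):
        src = pd.read_csv(
            w.resources.files("lipidgen") / "data" / "hdl_summary.tsv", sep="\t", dtype=str
        )
        dup = pd.concat([src, src.iloc[[0]]])
        path = tmp_path / "dup.tsv"
        dup.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="duplicate"):
            w.load_summary_table(path, HDL)

    def test_underflowing_p_flagged(self, tmp_path):
        src = pd.read_csv(
            w.resources.files("lipidgen") / "data" / "hdl_summary.tsv", sep="\t", dtype=str
        )
        src.loc[0, "EA_p"] = "1e-500"
        path = tmp_path / "uf.tsv"
        src.to_csv(path, sep="\t", index=False)
        table = w.load_summary_table(path, HDL)
        row = table[(table["snp"] == src.loc[0, "snp"]) & (table["population"] == "EA")].iloc[0]
        assert row["p"] > 0.0
        assert row["p_underflow"]


class TestRoundTrip:
    def test_summary_rows_identity(self, tmp_path, fixture_set):
        frame = fixture_set.tables["lnTG"].drop(columns=["p_underflow"])
        path = tmp_path / "rows.tsv"
        w.write_summary_rows(frame, path)
        back = w.read_summary_rows(path)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), frame.reset_index(drop=True), check_dtype=False
        )


class TestScenarioConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "scenario.yaml"
        cfg.write_text(
            """
population: AA
study: SIM
n_participants: 50
seed: 5
snp_freqs: {rs1: 0.25}
snp_effects:
  - {snp: rs1, trait: HDL-C, beta: 1.5}
linked_pairs:
  - {causal_snp: rs2, tag_snp: rs3, p_causal: 0.3, p_tag: 0.3, target_r2: 0.8}
medication_rate: 0.2
medication_offset: {LDL-C: -30.0}
covariates: {female_fraction: 0.6}
"""
        )
        sc = w.load_scenario(cfg)
        assert sc.population == "AA"
        assert sc.snp_effects[("rs1", "HDL-C")] == 1.5
        assert sc.linked_pairs[0].target_r2 == 0.8
        assert sc.covariates.female_fraction == 0.6

    def test_bad_config_raises(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("population: X\nstudy: S\nn_participants: 10\nbogus_key: 1\n")
        with pytest.raises(w.ConfigurationError):
            w.load_scenario(cfg)


class TestReproduce:
    def test_deterministic(self, fixture_set):
        r1 = w.reproduce(fixture_set)
        r2 = w.reproduce(fixture_set)
        assert w.report_to_json(r1) == w.report_to_json(r2)

    def test_vanishing_alpha_replicates_nothing(self, fixture_set):
        report = w.reproduce(fixture_set, alpha=1e-300)
        assert report["ea_replicated"] == 0


class TestCli:
    def test_reproduce_command_exits_zero(self):
        result = CliRunner().invoke(cli_main, ["reproduce"])
        assert result.exit_code == 0
        assert '"ea_replicated": 55' in result.output

    def test_power_command(self):
        result = CliRunner().invoke(
            cli_main, ["power", "--beta", "0", "--caf", "0.3", "--n", "100", "--sd", "15"]
        )
        assert result.exit_code == 0
        assert result.output.strip() == "0.0500"

    def test_simulate_then_assoc(self, tmp_path):
        cfg = tmp_path / "sc.yaml"
        cfg.write_text(
            """
population: EA
study: SIM
n_participants: 400
seed: 3
snp_freqs: {rs1: 0.4}
snp_effects:
  - {snp: rs1, trait: HDL-C, beta: 2.0}
"""
        )
        out = tmp_path / "participants.tsv"
        runner = CliRunner()
        r1 = runner.invoke(cli_main, ["simulate", "--config", str(cfg), "--out", str(out)])
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(
            cli_main,
            ["assoc", "--participants", str(out), "--snp", "rs1", "--trait", "HDL-C"],
        )
        assert r2.exit_code == 0, r2.output
        assert "rs1" in r2.output
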