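"""Scenario overrides, end-to-end runs and the command-line interface."""

from __future__ import annotations

import json

import numpy as np
import pytest
from click.testing import CliRunner

from alarmcea import SCENARIOS, apply_scenario, default_parameter_table, run_scenario
from alarmcea.cli import main


class TestApplyScenario:
    def test_base_is_identity(self, fixture_table):
        assert apply_scenario("base", fixture_table) == fixture_table

    @pytest.mark.parametrize(
        "name,expected",
        [
            ("SA1", {"p_prev": 0.5}),
            ("SA2", {"p_accept": 0.5}),
            ("SA3", {"d_decay": 0.0, "d_repair": 0.0}),
            ("SA4", {"h": 1.8}),
            ("SA5", {"p_injury_func": 0.91, "p_injury_nonfunc": 0.91}),
        ],
    )
    def test_overrides_pin_fixed_values(self, fixture_table, name, expected):
        table = apply_scenario(name, fixture_table)
        for param, value in expected.items():
            spec = table[param].spec
            assert spec.is_fixed and spec.hyperparameters == (value,)
        # everything else untouched
        for param in fixture_table.names():
            if param not in expected:
                assert table[param] == fixture_table[param]

    def test_unknown_scenario_lists_valid_names(self, fixture_table):
        with pytest.raises(KeyError, match="SA1"):
            apply_scenario("SA9", fixture_table)

    def test_sa5_severity_equalisation_flag(self, fixture_table):
        table = apply_scenario("SA5", fixture_table, equalise_severity=True)
        assert table["severity_split_nonfunc"].spec == table["severity_split_func"].spec


class TestRunScenario:
    def test_repeat_runs_are_identical(self, small_inputs):
        a = run_scenario("base", inputs=small_inputs, n_draws=64, seed=11)
        b = run_scenario("base", inputs=small_inputs, n_draws=64, seed=11)
        assert a.frontier.status == b.frontier.status
        assert np.array_equal(a.psa.qalys, b.psa.qalys)
        assert np.array_equal(a.ceac.probabilities, b.ceac.probabilities)
        assert a.evpi.per_decision == b.evpi.per_decision

    def test_sa3_freezes_alarm_states(self, small_inputs):
        """With decay and repair at zero no probability mass crosses between
        functioning and non-functioning alarm states in stage 2."""
        from alarmcea import Settings, TreeResult, run_preschool, sample_draw
        from alarmcea.scenarios import apply_scenario

        table = apply_scenario("SA3", small_inputs.table)
        draw = sample_draw(table, np.random.default_rng(0), small_inputs.utility_norms)
        result = run_preschool(TreeResult(0.85, 0.0), draw, small_inputs.life_table)
        func = result.trace[:, 0] + result.trace[:, 2]
        nonfunc = result.trace[:, 1] + result.trace[:, 3]
        # mass only leaves each alarm branch (to death), never crosses
        assert np.all(np.diff(func) <= 1e-15)
        assert np.all(np.diff(nonfunc) <= 1e-15)

    def test_scenarios_share_everything_but_the_overrides(self, small_inputs):
        """Metadata and the overridden rows are the only differences between
        scenario runs sharing a seed; notably SA2 leaves prevalence alone."""
        base = run_scenario("base", inputs=small_inputs, n_draws=64, seed=11)
        sa2 = run_scenario("SA2", inputs=small_inputs, n_draws=64, seed=11)
        assert base.psa.settings["scenario"] == "base"
        assert sa2.psa.settings["scenario"] == "SA2"
        meta_a = {k: v for k, v in base.psa.settings.items() if k != "scenario"}
        meta_b = {k: v for k, v in sa2.psa.settings.items() if k != "scenario"}
        assert meta_a == meta_b

    def test_sa4_reports_household_scale(self, small_inputs):
        sa4 = run_scenario("SA4", inputs=small_inputs, n_draws=64, seed=11)
        base = run_scenario("base", inputs=small_inputs, n_draws=64, seed=11)
        assert sa4.psa.settings["h"] == 1.8
        assert np.allclose(sa4.psa.qalys, 1.8 * base.psa.qalys, rtol=1e-12)

    def test_sa5_removes_the_injury_gradient(self, small_inputs):
        """Equal injury probabilities: QALY spread across strategies shrinks
        to the residual severity-split effect."""
        base = run_scenario("base", inputs=small_inputs, n_draws=64, seed=11)
        sa5 = run_scenario("SA5", inputs=small_inputs, n_draws=64, seed=11)
        spread = lambda run: np.ptp(run.psa.qalys.mean(axis=0))
        assert spread(sa5) < spread(base)
        # with severity splits equalised too, alarm status is irrelevant:
        flat = run_scenario(
            "SA5", inputs=small_inputs, n_draws=64, seed=11, equalise_severity=True
        )
        assert np.allclose(np.ptp(flat.psa.qalys, axis=1), 0.0, atol=1e-10)

    def test_nhs_pss_totals_never_exceed_public_sector(self, small_inputs):
        run = run_scenario("base", inputs=small_inputs, n_draws=64, seed=11,
                           perspective="NHS_PSS")
        nhs = run.psa.total_costs("NHS_PSS")
        pub = run.psa.total_costs("public_sector")
        assert np.all(nhs <= pub + 1e-9)

    def test_report_includes_ceac_columns(self, small_inputs):
        run = run_scenario("base", inputs=small_inputs, n_draws=64, seed=11)
        report = run.report()
        assert {"prob_ce_30000", "prob_ce_50000"} <= set(report.columns)
        assert report["prob_ce_30000"].sum() == pytest.approx(1.0, abs=1e-9)


class TestCli:
    def test_fixture_run_report_round_trip(self, tmp_path):
        runner = CliRunner()
        fixdir = tmp_path / "fixture"
        result = runner.invoke(
            main, ["fixture", "--out", str(fixdir), "--n-draws", "16", "--seed", "3"]
        )
        assert result.exit_code == 0, result.output
        for name in ("parameters.csv", "life_table.csv", "utility_norms.csv", "posterior.csv"):
            assert (fixdir / name).exists()

        outdir = tmp_path / "run"
        result = runner.invoke(
            main,
            [
                "run", "--scenario", "base", "--n-draws", "16", "--seed", "3",
                "--params", str(fixdir / "parameters.csv"),
                "--lifetable", str(fixdir / "life_table.csv"),
                "--norms", str(fixdir / "utility_norms.csv"),
                "--posterior", str(fixdir / "posterior.csv"),
                "--thresholds", "0:50000:10000",
                "--out", str(outdir),
            ],
        )
        assert result.exit_code == 0, result.output
        meta = json.loads((outdir / "metadata.json").read_text())
        assert meta["n_draws"] == 16 and meta["scenario"] == "base"
        assert (outdir / "psa.csv").exists() and (outdir / "ceac.csv").exists()
        evpi_out = json.loads((outdir / "evpi.json").read_text())
        assert evpi_out["per_decision"] >= 0.0

        repdir = tmp_path / "report"
        result = runner.invoke(
            main,
            ["report", "--psa", str(outdir / "psa.csv"),
             "--thresholds", "0:50000:10000", "--out", str(repdir)],
        )
        assert result.exit_code == 0, result.output
        import pandas as pd

        rebuilt = pd.read_csv(repdir / "frontier.csv")
        original = pd.read_csv(outdir / "frontier.csv")
        assert list(rebuilt["status"]) == list(original["status"])

    def test_run_uses_builtin_fixture_when_no_files_given(self, tmp_path):
        runner = CliRunner()
        outdir = tmp_path / "out"
        result = runner.invoke(
            main,
            ["run", "--scenario", "SA1", "--n-draws", "8", "--seed", "2",
             "--thresholds", "0:40000:20000", "--out", str(outdir)],
        )
        assert result.exit_code == 0, result.output
        assert (outdir / "frontier.csv").exists()
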