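import numpy as np
import pytest
from click.testing import CliRunner

from cardioloop.cli import main
from cardioloop.metrics import beat_metrics
from cardioloop.scenarios import (run_scenario, sensitivity_analysis,
                                  steady_state_reached)


def last(trace):
    return beat_metrics(trace).iloc[-1]


class TestDirectionalPathology:
    """Directions of change in the pathology presets vs the normal run."""

    def test_systolic_hf(self, baseline_trace, systolic_hf_trace):
        n, s = last(baseline_trace), last(systolic_hf_trace)
        assert s["ef"] < 0.7 * n["ef"]
        assert s["edv_lv"] > n["edv_lv"]
        assert s["lap"] > n["lap"]
        assert s["sap_sys"] < n["sap_sys"]
        assert s["sw_lv"] < n["sw_lv"]

    def test_diastolic_hf(self, baseline_trace, diastolic_hf_trace):
        n, d = last(baseline_trace), last(diastolic_hf_trace)
        assert abs(d["ef"] - n["ef"]) < 0.1 * n["ef"]  # EF preserved
        assert d["edv_lv"] < n["edv_lv"]
        assert d["lap"] > n["lap"]
        assert d["sv"] < n["sv"]

    def test_aortic_stenosis(self, baseline_trace, aortic_stenosis_trace):
        n, a = last(baseline_trace), last(aortic_stenosis_trace)
        assert a["esp_lv"] > 1.4 * n["esp_lv"]  # pressure load
        assert a["sap_sys"] < n["sap_sys"]
        assert a["sw_lv"] > n["sw_lv"]
        assert a["edv_lv"] > n["edv_lv"]
        assert a["ef"] < n["ef"]

    def test_aortic_stenosis_gradient(self, aortic_stenosis_trace):
        tr = aortic_stenosis_trace
        grad = np.max(tr["p_lv"] - tr["p_aortic_root"])
        assert grad > 60.0

    def test_aortic_regurgitation(self, baseline_trace,
                                  aortic_regurgitation_trace):
        n, a = last(baseline_trace), last(aortic_regurgitation_trace)
        assert a["sv"] > 1.25 * n["sv"]       # apparent SV rises
        assert a["sap_dia"] < n["sap_dia"]    # diastolic runoff
        assert a["sw_lv"] > n["sw_lv"]        # volume load
        assert a["edv_lv"] > n["edv_lv"]

    def test_regurgitant_diastolic_backflow(self, baseline_trace,
                                            aortic_regurgitation_trace):
        # competent valve: only a small closure transient of backflow;
        # 0.2 cm^2 leak: sustained diastolic backflow
        dt = 0.002

        def backflow(trace):
            q = trace["q_aortic"][trace.t > trace.t[-1] - 60.0 / 72.0]
            return -q[q < 0].sum() * dt

        assert backflow(baseline_trace) < 2.0
        assert backflow(aortic_regurgitation_trace) > 20.0

    def test_exercise_output(self, exercise_trace):
        assert last(exercise_trace)["co"] > 10.0

    def test_all_presets_reach_steady_state(self, baseline_trace,
                                            systolic_hf_trace,
                                            exercise_trace):
        for tr in (baseline_trace, systolic_hf_trace, exercise_trace):
            assert steady_state_reached(tr)


class TestRunScenario:
    def test_report_contains_key_metrics(self, normal_config):
        result = run_scenario("normal", duration=6.0)
        for token in ("CO", "SAP", "LVEF", "LVSW", "LVEDV", "LVESP"):
            assert token in result.report
        assert result.metrics["hr"] == pytest.approx(72.0, rel=1e-6)

    def test_unknown_scenario_lists_names(self):
        with pytest.raises(KeyError, match="valid"):
            run_scenario("no_such_scenario")


class TestSensitivity:
    def test_blood_volume_dominates(self, normal_config):
        df = sensitivity_analysis(
            ["globals.blood_volume", "chambers.lv.e_max",
             "baroreflex.gain_hr"],
            duration=25.0)
        by_param = df.groupby("parameter")["s_norm"].apply(
            lambda s: s.abs().max())
        assert by_param["globals.blood_volume"] == by_param.max()
        # a parameter with no downstream connection (reflex disabled)
        assert by_param["baroreflex.gain_hr"] == pytest.approx(0.0, abs=1e-9)
        assert set(df["output"]) == {"lvesp", "rvesp", "lap", "rap",
                                     "lvsw", "rvsw", "co"}

    def test_near_linear_response(self, normal_config):
        a = sensitivity_analysis(["chambers.lv.e_max"], rel_step=0.05,
                                 duration=25.0)
        b = sensitivity_analysis(["chambers.lv.e_max"], rel_step=0.10,
                                 duration=25.0)
        sa = a[a.output == "co"]["s_norm"].iloc[0]
        sb = b[b.output == "co"]["s_norm"].iloc[0]
        assert sa == pytest.approx(sb, rel=0.5)

    def test_headline_filter(self, normal_config):
        df = sensitivity_analysis(["baroreflex.gain_hr"], duration=6.0)
        assert not df["headline"].any()


class TestCli:
    def test_run_writes_csv(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "trace.csv"
        result = runner.invoke(main, ["run", "--preset", "normal",
                                      "--duration", "1.0",
                                      "--out", str(out)])
        assert result.exit_code == 0, result.output
        text = out.read_text()
        assert text.startswith("# units:")
        assert "p_lv" in text and "sat_pulm_artery" in text

    def test_scenario_report(self):
        runner = CliRunner()
        result = runner.invoke(main, ["scenario", "normal",
                                      "--duration", "4.0"])
        assert result.exit_code == 0, result.output
        assert "LVEF" in result.output

    def test_unknown_scenario_fails_cleanly(self):
        runner = CliRunner()
        result = runner.invoke(main, ["scenario", "bogus"])
        assert result.exit_code != 0
        assert "unknown scenario" in result.output

    def test_metrics_on_truncated_file(self, tmp_path):
        bad = tmp_path / "trace.csv"
        bad.write_text("t,p_nothing\n0.0,1.0\n")
        runner = CliRunner()
        result = runner.invoke(main, ["metrics", str(bad)])
        assert result.exit_code != 0
        assert "cannot compute metrics" in result.output

    def test_presets_listing(self):
        runner = CliRunner()
        result = runner.invoke(main, ["presets"])
        assert result.exit_code == 0
        assert "baseline" in result.output
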