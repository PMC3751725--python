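import copy
import warnings

import numpy as np
import pytest

from cardioloop import _kernel as K
from cardioloop.engine import SimTrace, assemble, run, step
from cardioloop.metrics import beat_metrics
from cardioloop.parameters import (ModelConfig, ScenarioOverride,
                                   apply_scenario, load_preset, set_path)

from conftest import make_two_segment_config


class TestAssemble:
    def test_total_volume_matches_configuration(self, normal_config):
        st = assemble(normal_config)
        assert st.total_volume() == pytest.approx(5600.0, abs=1e-9)

    def test_state_vector_composition(self, normal_config):
        st = assemble(normal_config)
        # 4 chambers + 26 segments, 34 branch flows, 4 valve fractions
        assert st.packed.ncomp == 30
        assert st.packed.nb == 34
        assert st.n_states == 68

    def test_deterministic(self, normal_config):
        a = assemble(normal_config)
        b = assemble(normal_config)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.sat, b.sat)

    def test_flows_zero_valves_closed(self, normal_config):
        st = assemble(normal_config)
        pk = st.packed
        assert np.all(st.x[pk.ncomp:pk.ncomp + pk.nb] == 0.0)
        assert np.all(st.x[pk.ncomp + pk.nb:] == 0.0)

    def test_removing_segments_shrinks_state(self, normal_config):
        data = normal_config.model_dump(by_alias=True)
        drop = {"right_coronary", "right_cor_micro"}
        data["segments"] = [s for s in data["segments"]
                            if s["name"] not in drop]
        data["branches"] = [b for b in data["branches"]
                            if b["source"] not in drop
                            and b["target"] not in drop]
        st = assemble(ModelConfig.model_validate(data))
        # two fewer volumes and three fewer branch flows
        assert st.n_states == 68 - 5

    def test_inconsistent_blood_volume_rejected(self, normal_config):
        cfg = copy.deepcopy(normal_config)
        cfg.globals_.blood_volume = 2000.0
        with pytest.raises(ValueError, match="inconsistent"):
            assemble(cfg)

    def test_low_damping_warns(self):
        with pytest.warns(UserWarning, match="lambda"):
            assemble(make_two_segment_config(damping_lambda=0.0))


class TestStep:
    def test_equilibrated_network_is_fixed_point(self):
        cfg = make_two_segment_config(perturbation=0.0, damping_lambda=0.5)
        st = assemble(cfg)
        x0 = st.x.copy()
        step(st, 10)
        assert np.max(np.abs(st.x - x0)) < 1e-10

    def test_flow_continuity_every_step(self, normal_config):
        # each volume change equals dt times the signed flow sum: the
        # implicit-Euler volume equations enforce junction continuity
        st = assemble(normal_config)
        step(st, 400)
        pk = st.packed
        dt = normal_config.globals_.dt
        for _ in range(5):
            v_before = st.x[:pk.ncomp].copy()
            step(st, 1)
            q = st.x[pk.ncomp:pk.ncomp + pk.nb]
            nf = np.zeros(pk.ncomp)
            np.subtract.at(nf, pk.b_up, q)
            np.add.at(nf, pk.b_dn, q)
            np.testing.assert_allclose(st.x[:pk.ncomp] - v_before, nf * dt,
                                       atol=1e-8)

    def test_volume_conserved_over_many_steps(self, normal_config):
        st = assemble(normal_config)
        step(st, 20000)
        assert abs(st.total_volume() - 5600.0) < 1e-6 * 5600.0


class TestWindkesselOracle:
    def test_relaxation_matches_analytic_exponential(self):
        cfg = make_two_segment_config(perturbation=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trace = run(cfg, 0.25, record_interval=5e-4)
        # rebase after the brief inertial start-up (flow begins at zero)
        settle = trace.t - trace.t[0] >= 0.005
        t = trace.t[settle] - trace.t[settle][0]
        dp = (trace["p_a"] - trace["p_b"])[settle]
        # tau = R_branch * C_a C_b / (C_a + C_b)
        tau = 0.05 * (2.0 * 50.0 / 52.0)
        expected = dp[0] * np.exp(-t / tau)
        keep = t < 2 * tau
        err = np.abs(dp[keep] - expected[keep]) / dp[0]
        assert err.max() < 0.005

    def test_windkessel_time_constant_fit(self):
        cfg = make_two_segment_config(perturbation=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trace = run(cfg, 0.2, record_interval=5e-4)
        settle = trace.t - trace.t[0] >= 0.005
        dp = (trace["p_a"] - trace["p_b"])[settle]
        slope = np.polyfit(trace.t[settle], np.log(dp), 1)[0]
        assert -1.0 / slope == pytest.approx(0.05 * 100.0 / 52.0, rel=0.005)


class TestRun:
    def test_zero_duration_empty_trace(self, normal_config):
        trace = run(normal_config, 0.0)
        assert len(trace) == 0

    def test_negative_duration_rejected(self, normal_config):
        with pytest.raises(ValueError):
            run(normal_config, -1.0)

    def test_bit_identical_reruns(self, normal_config):
        a = run(normal_config, 1.5, record_interval=0.001)
        b = run(normal_config, 1.5, record_interval=0.001)
        np.testing.assert_array_equal(a.data, b.data)

    def test_timed_event_applies_and_restores(self, normal_config):
        cfg = copy.deepcopy(normal_config)
        scen = ScenarioOverride(name="puff", timed_events=[
            {"t_start": 1.0, "t_end": 2.0,
             "path": "globals.intrathoracic_pressure", "value": 10.0}])
        cfg = apply_scenario(cfg, scen)
        trace = run(cfg, 3.0, record_interval=0.002)
        t = trace.t
        p_ivc = trace["p_ivc"]  # intrathoracic compartment
        during = p_ivc[(t > 1.05) & (t < 1.95)].mean()
        before = p_ivc[t < 0.95].mean()
        after = p_ivc[t > 2.3].mean()
        assert during > before + 5.0
        assert abs(after - before) < 4.0

    def test_staged_heart_rate_patch_shortens_beats(self, normal_config):
        cfg = copy.deepcopy(normal_config)
        cfg.staged = [{"t": 2.0, "patches": {"globals.heart_rate": 120.0}}]
        trace = run(cfg, 5.0, record_interval=0.002)
        periods = trace.beats["period"].to_numpy()
        assert periods[0] == pytest.approx(60.0 / 72.0)
        assert periods[-1] == pytest.approx(0.5, rel=1e-6)

    def test_rr_seed_reproducible_and_af_drops_output(self, normal_config):
        cfg = copy.deepcopy(normal_config)
        # atrial fibrillation: no atrial contraction, randomized RR
        for ch in ("la", "ra"):
            set_path(cfg, f"chambers.{ch}.e_max", 0.021)
            set_path(cfg, f"chambers.{ch}.e_min", 0.02)
        a = run(cfg, 12.0, record_interval=0.002, rr_seed=7)
        b = run(cfg, 12.0, record_interval=0.002, rr_seed=7)
        np.testing.assert_array_equal(a.data, b.data)
        sinus = run(normal_config, 12.0, record_interval=0.002)
        co_af = beat_metrics(a)["co"].iloc[-3:].mean()
        co_sinus = beat_metrics(sinus)["co"].iloc[-3:].mean()
        assert co_af < co_sinus

    def test_step_size_robustness(self, normal_config):
        co = {}
        for dt in (0.00025, 0.00005):
            cfg = copy.deepcopy(normal_config)
            cfg.globals_.dt = dt
            trace = run(cfg, 10.0, record_interval=0.002)
            co[dt] = beat_metrics(trace)["co"].iloc[-1]
        assert abs(co[0.00025] - co[0.00005]) < 0.01 * co[0.00005]


class TestExternalPressure:
    def test_groups(self, normal_config):
        cfg = copy.deepcopy(normal_config)
        cfg.globals_.intrathoracic_pressure = 7.0
        st = assemble(cfg)
        assert st.external_pressure("extrathoracic") == 0.0
        assert st.external_pressure("intrathoracic") == 7.0
        peri = st.external_pressure("pericardial")
        assert peri != 7.0  # includes the pericardial term

    def test_pericardial_suction_at_small_heart_volume(self, normal_config):
        cfg = copy.deepcopy(normal_config)
        cfg.globals_.intrathoracic_pressure = 0.0
        st = assemble(cfg)
        st.x[:4] = 5.0  # nearly empty chambers
        assert st.external_pressure("pericardial") < 0.0

    def test_unknown_group_rejected(self, normal_config):
        st = assemble(normal_config)
        with pytest.raises(ValueError, match="unknown"):
            st.external_pressure("abdominal")


class TestTrace:
    def test_csv_round_trip(self, tmp_path, normal_config):
        trace = run(normal_config, 1.0, record_interval=0.005)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path, comment="#")
        assert list(df.columns) == trace.columns
        np.testing.assert_allclose(df.to_numpy(), trace.data, rtol=1e-6)

    def test_total_volume_column_sum(self, baseline_trace):
        tv = baseline_trace.total_volume()
        assert tv.shape[0] == len(baseline_trace)

    def test_event_topology_change_rejected(self, normal_config):
        st = assemble(normal_config)
        data = normal_config.model_dump(by_alias=True)
        data["segments"] = data["segments"][:-1]
        data["branches"] = data["branches"][:-2]
        from cardioloop.engine import _repack
        with pytest.raises(ValueError, match="topology"):
            _repack(st, ModelConfig.model_validate(data))
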