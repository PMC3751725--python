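import numpy as np
import pytest

from cardioloop.cardiac import (chamber_pressure, double_hill_activation,
                                double_hill_norm_constant, ecg_trace,
                                effective_emax, passive_pressure,
                                pericardial_pressure, septal_coupled_pressure)

T = 60.0 / 72.0
VENT = dict(alpha1=0.303, alpha2=0.508, n1=1.32, n2=27.4)


def act(t, **kw):
    p = {**VENT, **kw}
    return double_hill_activation(t, T, p["alpha1"], p["alpha2"],
                                  p["n1"], p["n2"])


class TestDoubleHill:
    def test_zero_at_cycle_start(self):
        assert act(0.0) == 0.0

    def test_normalized_peak_is_one(self):
        t = np.linspace(0.0, T, 20000, endpoint=False)
        assert abs(act(t).max() - 1.0) < 1e-6

    def test_peak_location_matches_grid_search_oracle(self):
        # frozen from a 1e5-point brute-force scan of the default waveform
        t = np.linspace(0.0, T, 20000, endpoint=False)
        t_star = t[np.argmax(act(t))]
        assert abs(t_star / T - 0.43928) < 1e-3

    def test_bounded_in_unit_interval(self):
        t = np.linspace(0.0, T, 5000, endpoint=False)
        a = act(t)
        assert np.all(a >= 0.0) and np.all(a <= 1.0 + 1e-12)

    @pytest.mark.parametrize("kw", [dict(period=-1.0), dict(period=0.0)])
    def test_nonpositive_period_rejected(self, kw):
        with pytest.raises(ValueError):
            double_hill_activation(0.1, kw["period"], 0.3, 0.5, 1.32, 27.4)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            double_hill_norm_constant(T, -0.1, 0.5, 1.32, 27.4)

    def test_norm_constant_reused(self):
        norm = double_hill_norm_constant(T, 0.303, 0.508, 1.32, 27.4)
        a1 = double_hill_activation(0.3, T, 0.303, 0.508, 1.32, 27.4, norm)
        a2 = double_hill_activation(0.3, T, 0.303, 0.508, 1.32, 27.4)
        assert a1 == pytest.approx(a2)


class TestStarling:
    def test_identity_below_threshold(self):
        assert effective_emax(2.8, 110.0, 180.0, 120.0) == 2.8

    def test_non_increasing_in_volume(self):
        v = np.linspace(0.0, 400.0, 200)
        e = effective_emax(2.8, v, 180.0, 120.0)
        assert np.all(np.diff(e) <= 1e-12)

    def test_smooth_at_threshold(self):
        lo = effective_emax(2.8, 180.0 - 1e-7, 180.0, 120.0)
        hi = effective_emax(2.8, 180.0 + 1e-7, 180.0, 120.0)
        assert abs(hi - lo) < 1e-8


class TestPassivePressure:
    def test_zero_at_unstressed_volume(self):
        assert passive_pressure(35.0, 0.05, 35.0, 80.0) == 0.0

    def test_slope_at_unstressed_volume_is_emin(self):
        h = 1e-4
        slope = (passive_pressure(35.0 + h, 0.05, 35.0, 80.0)
                 - passive_pressure(35.0 - h, 0.05, 35.0, 80.0)) / (2 * h)
        assert slope == pytest.approx(0.05, rel=1e-6)

    def test_convexity_ratio_closed_form(self):
        # p(v0 + 2*phi) / p(v0 + phi) = (e^2 - 1)/(e - 1) for this form
        phi = 80.0
        ratio = (passive_pressure(35.0 + 2 * phi, 0.05, 35.0, phi)
                 / passive_pressure(35.0 + phi, 0.05, 35.0, phi))
        assert ratio == pytest.approx(3.718281828459045, rel=1e-9)


class TestChamberPressure:
    def test_relaxed_at_unstressed_volume(self):
        assert chamber_pressure(0.0, 2.8, 10.0, 10.0, 0.05, 120.0,
                                0.002, 0.0) == 0.0

    def test_fully_activated_elastance_line(self):
        # measured end-systolic elastance 2.43 over a 50 ml stressed volume
        p = chamber_pressure(1.0, 2.43, 60.0, 10.0, 0.05, 120.0, 0.002, 0.0)
        assert p == pytest.approx(121.5, rel=1e-12)

    def test_wall_viscosity_raises_pressure_during_filling(self):
        base = chamber_pressure(0.2, 2.8, 80.0, 10.0, 0.05, 120.0, 0.01, 0.0)
        filling = chamber_pressure(0.2, 2.8, 80.0, 10.0, 0.05, 120.0, 0.01,
                                   200.0)
        assert filling > base


class TestSeptum:
    def test_rigid_septum_limit(self):
        plv = septal_coupled_pressure(2.0, 100.0, 20.0, esv0=1e9)
        assert plv == pytest.approx(200.0, rel=1e-6)

    def test_equal_stiffness_half_weights(self):
        plv = septal_coupled_pressure(2.0, 100.0, 20.0, esv0=1.0)
        assert plv == pytest.approx(0.5 * 200.0 + 0.5 * 20.0)

    def test_worked_example(self):
        # Esv = 10 * 2 = 20: plv = (20/22)*200 + (2/22)*20
        plv = septal_coupled_pressure(2.0, 100.0, 20.0, esv0=10.0)
        assert plv == pytest.approx(183.6363636, rel=1e-8)

    def test_nonpositive_elastance_rejected(self):
        with pytest.raises(ValueError):
            septal_coupled_pressure(0.0, 100.0, 20.0, 10.0)


class TestPericardium:
    def test_small_volume_approaches_pmin(self):
        p = pericardial_pressure(0.0, 755.0, 1.75, 30.0, -2.0)
        assert -2.0 < p < -1.99

    def test_monotone_in_volume(self):
        v = np.linspace(300.0, 1200.0, 300)
        p = pericardial_pressure(v, 755.0, 1.75, 30.0, -2.0)
        assert np.all(np.diff(p) > 0)

    def test_doubling_phi_halves_log_slope(self):
        v = np.array([700.0, 720.0])
        s1 = np.diff(np.log(pericardial_pressure(v, 755.0, 1.75, 30.0, -2.0)
                            + 2.0))[0]
        s2 = np.diff(np.log(pericardial_pressure(v, 755.0, 1.75, 60.0, -2.0)
                            + 2.0))[0]
        assert s1 == pytest.approx(2 * s2, rel=1e-9)

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(ValueError):
            pericardial_pressure(700.0, 755.0, 1.75, 0.0, -2.0)


class TestEcg:
    CHAMBERS = [(0.12, 0.22, 1.9, 11.0, 0.0),    # atrium
                (0.22, 0.42, 3.0, 25.0, 0.16)]   # ventricle

    def test_zero_weights_flat(self):
        t = np.linspace(0.0, T, 500, endpoint=False)
        out = ecg_trace(t, T, self.CHAMBERS, [0.0, 0.0])
        assert np.all(out == 0.0)

    def test_atrial_peak_precedes_ventricular_by_av_interval(self):
        t = np.linspace(0.0, T, 8000, endpoint=False)
        atr = ecg_trace(t, T, self.CHAMBERS, [1.0, 0.0])
        ven = ecg_trace(t, T, self.CHAMBERS, [0.0, 1.0])
        dt_peaks = t[np.argmax(ven)] - t[np.argmax(atr)]
        # both waveforms carry the same electromechanical shift; the peak
        # separation is the AV onset delay plus the difference of the two
        # waveform peak positions
        assert 0.15 < dt_peaks < 0.45
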