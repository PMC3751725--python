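"""Derived clinical beat metrics from simulation traces.

All metrics are computed per complete beat, using the beat boundaries that
the solver records.  Reported values follow catheter-lab conventions:
ejection fraction from EDV/ESV, stroke work as the pressure-volume loop
area, Tau from a monoexponential fit of the isovolumic pressure decay, the
Tei index from valve opening/closing times, and Ea = ESP/SV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["stroke_work", "ejection_fraction", "tau_decay", "beat_metrics",
           "summary_metrics"]


def stroke_work(p, v):
    """Signed pressure-volume loop area, mmHg*ml.

    Positive for a loop traversed counterclockwise in (p, v) axes, i.e. a
    working ventricle ejecting at high pressure and filling at low pressure.
    The loop is closed between the last and first samples.
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(p) < 3:
        raise ValueError("need at least 3 samples for a loop area")
    pc = np.append(p, p[0])
    vc = np.append(v, v[0])
    return -np.trapezoid(pc, vc)


def ejection_fraction(edv, esv):
    """Ejection fraction in percent; requires EDV > 0 and ESV <= EDV."""
    if edv <= 0:
        raise ValueError("EDV must be positive")
    return 100.0 * (edv - esv) / edv


def tau_decay(t, p, p_floor=1.0):
    """Relaxation constant of a monoexponential pressure decay, ms.

    Fits ``p(t) = p(0) * exp(-t/tau)`` (zero-asymptote variant) by linear
    regression on log pressure; samples below ``p_floor`` are excluded.
    Returns NaN if the window is too short.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    mask = p > p_floor
    if mask.sum() < 4:
        return np.nan
    slope = np.polyfit(t[mask], np.log(p[mask]), 1)[0]
    if slope >= 0:
        return np.nan
    return -1000.0 / slope


def _crossing(t, sig, level, direction, t_after=None):
    """First time ``sig`` crosses ``level`` in ``direction`` (+1 up, -1 down)."""
    s = np.asarray(sig) - level
    if direction > 0:
        hits = np.where((s[:-1] <= 0) & (s[1:] > 0))[0]
    else:
        hits = np.where((s[:-1] >= 0) & (s[1:] < 0))[0]
    for i in hits:
        tc = t[i] + (t[i + 1] - t[i]) * (0.0 - s[i]) / (s[i + 1] - s[i])
        if t_after is None or tc >= t_after:
            return tc
    return np.nan


def _sdm(x):
    """(systolic, diastolic, mean) of a pressure signal over one beat."""
    return float(np.max(x)), float(np.min(x)), float(np.mean(x))


def beat_metrics(trace, v0_lv=None, v0_rv=None) -> pd.DataFrame:
    """Per-beat clinical metrics for every complete beat in the trace.

    Requires chamber signals in the trace; raises if no complete beat is
    available.  ``v0_lv``/``v0_rv`` (unstressed volumes, for the measured
    end-systolic elastance) default to the values in the trace's config.
    """
    if "p_lv" not in trace:
        raise ValueError("trace has no cardiac signals")
    cfg = trace.config
    if v0_lv is None and cfg.chambers is not None:
        v0_lv = cfg.chambers["lv"].v0
        v0_rv = cfg.chambers["rv"].v0
    t = trace.t
    beats = trace.beats
    rows = []
    dt = t[1] - t[0] if len(t) > 1 else np.nan
    for _, beat in beats.iterrows():
        t0, period = beat.t_start, beat.period
        if t0 < t[0] - 1e-9 or t0 + period > t[-1] + 1e-6:
            continue
        m = (t >= t0 - 1e-9) & (t < t0 + period - 1e-9)
        if m.sum() < 10:
            continue
        tb = t[m]
        p_lv, v_lv = trace["p_lv"][m], trace["v_lv"][m]
        p_rv, v_rv = trace["p_rv"][m], trace["v_rv"][m]
        row = {"t_start": t0, "period": period, "hr": 60.0 / period}
        # left ventricle; end-systolic pressure reported as the mean
        # ventricular pressure over the ejection phase, which stays on the
        # end-systolic elastance line for normal and stenotic afterloads
        edv, esv = float(v_lv.max()), float(v_lv.min())
        q_av_b = trace["q_aortic"][m]
        eject = q_av_b > 0.02 * max(float(np.max(q_av_b)), 1e-9)
        esp = float(np.mean(p_lv[eject])) if eject.any() \
            else float(p_lv[int(np.argmin(v_lv))])
        sv = edv - esv
        row.update(edv_lv=edv, esv_lv=esv, sv=sv, esp_lv=esp,
                   ef=ejection_fraction(edv, esv),
                   sw_lv=stroke_work(p_lv, v_lv))
        dpdt = np.gradient(p_lv, tb)
        row["dpdt_max"] = float(dpdt.max())
        row["dpdt_min"] = float(dpdt.min())
        # right ventricle
        edv_r, esv_r = float(v_rv.max()), float(v_rv.min())
        q_pv_b = trace["q_pulmonary"][m]
        eject_r = q_pv_b > 0.02 * max(float(np.max(q_pv_b)), 1e-9)
        esp_r = float(np.mean(p_rv[eject_r])) if eject_r.any() \
            else float(p_rv[int(np.argmin(v_rv))])
        row.update(edv_rv=edv_r, esv_rv=esv_r, esp_rv=esp_r,
                   sv_rv=edv_r - esv_r,
                   ef_rv=ejection_fraction(edv_r, esv_r),
                   sw_rv=stroke_work(p_rv, v_rv))
        dpdt_r = np.gradient(p_rv, tb)
        row["dpdt_max_rv"] = float(dpdt_r.max())
        row["dpdt_min_rv"] = float(dpdt_r.min())
        # cardiac output from aortic valve flow
        row["co"] = float(np.mean(trace["q_aortic"][m])) * 60.0 / 1000.0
        # site pressures
        sap = _sdm(trace["p_ascending_aorta"][m])
        pap = _sdm(trace["p_pulm_artery"][m]) if "p_pulm_artery" in trace \
            else (np.nan,) * 3
        row.update(sap_sys=sap[0], sap_dia=sap[1], sap_mean=sap[2],
                   pap_sys=pap[0], pap_dia=pap[1], pap_mean=pap[2],
                   lap=float(np.mean(trace["p_la"][m])),
                   rap=float(np.mean(trace["p_ra"][m])),
                   la_vmin=float(trace["v_la"][m].min()),
                   la_vmax=float(trace["v_la"][m].max()),
                   ra_vmin=float(trace["v_ra"][m].min()),
                   ra_vmax=float(trace["v_ra"][m].max()))
        # valve timing from flow onset/cessation (Doppler convention): the
        # gradual-valve open fraction also drifts shut in diastasis, which
        # would conflate diastolic drift with the isovolumic intervals
        q_mv, q_av = trace["q_mitral"][m], trace["q_aortic"][m]
        thr_mv = 0.02 * float(np.max(q_mv))
        thr_av = 0.02 * float(np.max(q_av))
        t_avo = _crossing(tb, q_av, thr_av, +1)
        t_mvc = _crossing(tb[tb < t_avo], q_mv[tb < t_avo], thr_mv, -1) \
            if not np.isnan(t_avo) else np.nan
        t_avc = _crossing(tb, q_av, thr_av, -1, t_after=t_avo)
        t_mvo = _crossing(tb, q_mv, thr_mv, +1, t_after=t_avc)
        if not np.any(np.isnan([t_mvc, t_avo, t_avc, t_mvo])):
            ict = t_avo - t_mvc
            et = t_avc - t_avo
            irt = t_mvo - t_avc
            row["tei"] = (ict + irt) / et if et > 0 else np.nan
            row["et"] = et
        else:
            row["tei"] = np.nan
            row["et"] = np.nan
        # Tau: isovolumic relaxation from dp/dt_min to mitral opening
        t_dpmin = tb[int(np.argmin(dpdt))]
        t_end = t_mvo if not np.isnan(t_mvo) and t_mvo > t_dpmin \
            else t_dpmin + 0.06
        w = (tb >= t_dpmin + 2 * dt) & (tb <= t_end)
        row["tau_ms"] = tau_decay(tb[w], p_lv[w]) if w.sum() >= 4 else np.nan
        # coupling
        row["ea"] = esp / sv if sv > 0 else np.nan
        row["ees"] = esp / (esv - v0_lv) if esv > v0_lv else np.nan
        row["ees_ea"] = row["ees"] / row["ea"] if row["ea"] else np.nan
        row["ees_rv"] = esp_r / (esv_r - v0_rv) if esv_r > v0_rv else np.nan
        # oxygen
        if "sat_pulm_artery" in trace:
            row["svo2"] = float(np.mean(trace["sat_pulm_artery"][m]))
            row["sao2"] = float(np.mean(trace["sat_ascending_aorta"][m]))
        rows.append(row)
    if not rows:
        raise ValueError("trace contains no complete beat")
    return pd.DataFrame(rows)


def summary_metrics(trace) -> dict:
    """Metrics of the last complete beat (steady-state reporting beat)."""
    return beat_metrics(trace).iloc[-1].to_dict()
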