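"""Scenario runner and one-at-a-time sensitivity analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cardioloop.engine import run
from cardioloop.metrics import beat_metrics, summary_metrics
from cardioloop.parameters import (ModelConfig, get_path, load_preset,
                                   set_path)

__all__ = ["ScenarioResult", "run_scenario", "sensitivity_analysis",
           "steady_state_reached"]

#: headline output variables of the sensitivity analysis
SENSITIVITY_OUTPUTS = ("lvesp", "rvesp", "lap", "rap", "lvsw", "rvsw", "co")

_METRIC_KEYS = {"lvesp": "esp_lv", "rvesp": "esp_rv", "lap": "lap",
                "rap": "rap", "lvsw": "sw_lv", "rvsw": "sw_rv", "co": "co"}


@dataclass
class ScenarioResult:
    name: str
    trace: object
    metrics: dict
    report: str


def steady_state_reached(trace, rel_tol=0.005, n_beats=3) -> bool:
    """True when beat-averaged cardiac output varies < rel_tol between the
    last ``n_beats`` beats."""
    bm = beat_metrics(trace)
    if len(bm) < n_beats + 1:
        return False
    co = bm["co"].to_numpy()[-n_beats:]
    return bool(np.ptp(co) <= rel_tol * np.mean(co))


def run_scenario(name: str, duration: float = 60.0,
                 record_interval: float = 0.002,
                 record_tail: float | None = None,
                 rr_seed=None) -> ScenarioResult:
    """Run a named preset scenario to steady state and report key metrics.

    ``record_tail`` optionally restricts the returned trace to the last so
    many seconds (the full duration is still simulated).
    """
    config = load_preset(name)
    trace = run(config, duration, record_interval=record_interval,
                rr_seed=rr_seed)
    if record_tail is not None:
        keep = trace.t >= trace.t[-1] - record_tail
        trace.data = trace.data[keep]
    m = summary_metrics(trace)
    report = _format_report(name, m)
    return ScenarioResult(name=name, trace=trace, metrics=m, report=report)


def _format_report(name: str, m: dict) -> str:
    lines = [
        f"scenario: {name}",
        f"  HR      {m['hr']:6.1f} min^-1",
        f"  CO      {m['co']:6.2f} l/min",
        f"  SAP     {m['sap_sys']:.0f}/{m['sap_dia']:.0f}({m['sap_mean']:.0f}) mmHg",
        f"  PAP     {m['pap_sys']:.0f}/{m['pap_dia']:.0f}({m['pap_mean']:.0f}) mmHg",
        f"  LAP     {m['lap']:6.1f} mmHg   RAP {m['rap']:5.1f} mmHg",
        f"  LVEF    {m['ef']:6.1f} %      RVEF {m['ef_rv']:5.1f} %",
        f"  LVSV    {m['sv']:6.1f} ml",
        f"  LVSW    {m['sw_lv']:6.0f} mmHg*ml",
        f"  LVEDV   {m['edv_lv']:6.1f} ml",
        f"  LVESP   {m['esp_lv']:6.1f} mmHg",
    ]
    if "svo2" in m and np.isfinite(m.get("svo2", np.nan)):
        lines.append(f"  SaO2    {m['sao2']:6.1f} %    SvO2 {m['svo2']:5.1f} %")
    return "\n".join(lines)


def _collect_outputs(trace) -> dict:
    m = summary_metrics(trace)
    return {name: float(m[_METRIC_KEYS[name]]) for name in SENSITIVITY_OUTPUTS}


def sensitivity_analysis(parameters, outputs=SENSITIVITY_OUTPUTS,
                         config: ModelConfig | None = None,
                         rel_step: float = 0.10, duration: float = 60.0,
                         filter_threshold: float = 0.10) -> pd.DataFrame:
    """One-at-a-time sensitivity: each parameter is increased by ``rel_step``.

    Outputs are evaluated after ``duration`` seconds (hemodynamic steady
    state).  Both the raw sensitivity ``S = dy/dx`` and the normalized
    ``S_norm = (dy/y)/(dx/x)`` are reported; rows with
    ``|S_norm| < filter_threshold`` for every output are excluded from the
    ``headline`` column (matching the convention of dropping parameters with
    less than 10% sensitivity).
    """
    base = config if config is not None else load_preset("normal")
    trace0 = run(base, duration, record_interval=0.002)
    y0 = _collect_outputs(trace0)
    rows = []
    for path in parameters:
        x0 = float(get_path(base, path))
        import copy
        cfg = copy.deepcopy(base)
        set_path(cfg, path, x0 * (1.0 + rel_step))
        trace = run(cfg, duration, record_interval=0.002)
        y = _collect_outputs(trace)
        for name in outputs:
            dy = y[name] - y0[name]
            dx = x0 * rel_step
            if y0[name] == 0.0:
                s_norm = np.nan
            else:
                s_norm = (dy / y0[name]) / rel_step
            rows.append({"parameter": path, "output": name,
                         "baseline": y0[name], "perturbed": y[name],
                         "s_raw": dy / dx if dx != 0 else np.nan,
                         "s_norm": s_norm,
                         "headline": abs(s_norm) >= filter_threshold
                         if np.isfinite(s_norm) else False})
    df = pd.DataFrame(rows)
    return df.reindex(df["s_norm"].abs().sort_values(ascending=False).index)
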