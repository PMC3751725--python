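"""Cardiac chamber mechanics.

Each chamber is driven by a normalized double-Hill activation waveform that
blends an active elastance limb with a nonlinear passive limb.  The module
also provides the load-dependent contractility roll-off (Starling), the
pressure-transmission septum, the exponential pericardium and the schematic
ECG output.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "double_hill_raw",
    "double_hill_norm_constant",
    "double_hill_activation",
    "effective_emax",
    "passive_pressure",
    "chamber_pressure",
    "septal_coupled_pressure",
    "pericardial_pressure",
    "ecg_trace",
]


def double_hill_raw(t, tau1, tau2, n1, n2):
    """Unnormalized product of a rising and a falling Hill sigmoid.

    ``g1 = (t/tau1)^n1 / (1 + (t/tau1)^n1)`` rises from 0 toward 1,
    ``g2 = 1 / (1 + (t/tau2)^n2)`` falls from 1 toward 0.
    """
    t = np.asarray(t, dtype=float)
    x1 = (t / tau1) ** n1
    g1 = x1 / (1.0 + x1)
    g2 = 1.0 / (1.0 + (t / tau2) ** n2)
    return g1 * g2


def double_hill_norm_constant(period, alpha1, alpha2, n1, n2, npts=4096):
    """Constant that rescales the raw double-Hill product to peak at 1.

    Must be recomputed whenever the period, the cycle fractions alpha1/alpha2
    or the exponents change.
    """
    if period <= 0.0:
        raise ValueError("period must be positive")
    if alpha1 <= 0.0 or alpha2 <= 0.0:
        raise ValueError("alpha1 and alpha2 must be positive")
    t = np.linspace(0.0, period, npts, endpoint=False)
    peak = double_hill_raw(t, alpha1 * period, alpha2 * period, n1, n2).max()
    return 1.0 / peak


def double_hill_activation(t_cycle, period, alpha1, alpha2, n1, n2, norm=None):
    """Normalized activation in [0, 1] at time ``t_cycle`` within the cycle.

    ``alpha1`` and ``alpha2`` are fractions of the period.  ``norm`` may be
    passed to avoid recomputing the normalization constant.
    """
    if period <= 0.0:
        raise ValueError("period must be positive")
    if alpha1 <= 0.0 or alpha2 <= 0.0:
        raise ValueError("alpha1 and alpha2 must be positive")
    if norm is None:
        norm = double_hill_norm_constant(period, alpha1, alpha2, n1, n2)
    return norm * double_hill_raw(t_cycle, alpha1 * period, alpha2 * period, n1, n2)


def effective_emax(e_max, v, v_threshold, width):
    """Maximum elastance with contractility roll-off during volume overload.

    Below ``v_threshold`` the configured ``e_max`` is returned unchanged;
    above it a smooth monotone factor ``1 / (1 + ((v - v_th)/width)^2)``
    reduces contractile strength, curving the end-systolic pressure-volume
    relation downward at high volumes.
    """
    v = np.asarray(v, dtype=float)
    excess = np.maximum(v - v_threshold, 0.0) / width
    return e_max / (1.0 + excess * excess)


def passive_pressure(v, e_min, v0, phi):
    """End-diastolic (passive) pressure-volume relation.

    ``p = e_min * phi * (exp((v - v0)/phi) - 1)``: zero at the unstressed
    volume, slope ``e_min`` there, convex increase above it.
    """
    v = np.asarray(v, dtype=float)
    return e_min * phi * (np.exp((v - v0) / phi) - 1.0)


def chamber_pressure(activation, e_max_eff, v, v0, e_min, phi, r_wall, dv_dt):
    """Instantaneous chamber pressure before septal/pericardial additions.

    Convex blend of the active and passive limbs by the activation value
    plus a viscous wall term proportional to the volume rate of change.
    """
    p_act = e_max_eff * (v - v0)
    p_pas = passive_pressure(v, e_min, v0, phi)
    return activation * p_act + (1.0 - activation) * p_pas + r_wall * dv_dt


def septal_coupled_pressure(elv_t, vlv, prv, esv0):
    """Left ventricular pressure with pressure transmission through the septum.

    ``plv = [Esv/(Esv+elv)] * elv * vlv + [elv/(Esv+elv)] * prv`` with the
    septal stiffness stiffening in proportion to the instantaneous left
    ventricular elastance, ``Esv = esv0 * elv``.  The symmetric relation with
    left/right roles swapped yields the right ventricular pressure; the atrial
    septum is treated the same way but with a constant stiffness.
    """
    if elv_t <= 0.0:
        raise ValueError("instantaneous elastance must be positive")
    esv = esv0 * elv_t
    denom = esv + elv_t
    return (esv / denom) * elv_t * vlv + (elv_t / denom) * prv


def pericardial_pressure(v_heart_total, v_pc0, p_scale, phi, p_min):
    """Exponential pericardial pressure-volume relation.

    ``p = p_min + p_scale * exp((V - v_pc0)/phi)``.  The minimum pressure may
    be negative, as measured during hypovolemia or intrathoracic pressure
    swings.
    """
    if phi <= 0.0:
        raise ValueError("phi must be positive")
    v = np.asarray(v_heart_total, dtype=float)
    return p_min + p_scale * np.exp((v - v_pc0) / phi)


def ecg_trace(t_cycle, period, chamber_params, weights, delay=0.06):
    """Schematic ECG: weighted sum of the four activation waveforms.

    Electrical activity precedes mechanics by the electromechanical delay, so
    each activation is evaluated ``delay`` seconds ahead of the current cycle
    time.  Display only -- the trace feeds nothing back into the physiology.

    ``chamber_params`` is a sequence of (alpha1, alpha2, n1, n2, onset) tuples
    in the order matching ``weights``.
    """
    t_cycle = np.asarray(t_cycle, dtype=float)
    out = np.zeros_like(t_cycle)
    for (a1, a2, n1, n2, onset), w in zip(chamber_params, weights):
        if w == 0.0:
            continue
        norm = double_hill_norm_constant(period, a1, a2, n1, n2)
        t_rel = np.mod(t_cycle + delay - onset, period)
        out = out + w * double_hill_activation(t_rel, period, a1, a2, n1, n2, norm)
    return out
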