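"""Baroreceptor reflex.

Proportional control with first-order sensing: the running mean arterial
pressure is low-pass filtered, and the (setpoint - MAP) error drives three
bounded multipliers applied to heart rate, ventricular maximum elastance and
systemic arteriolar resistance.  With the reflex disabled all multipliers
stay at exactly 1 and the simulation is bit-identical to a build without it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["filter_map", "reflex_update"]


def filter_map(map_filtered, map_instant, dt, time_constant):
    """First-order low-pass update of the sensed mean arterial pressure."""
    if time_constant <= 0.0:
        raise ValueError("time_constant must be positive")
    return map_filtered + dt * (map_instant - map_filtered) / time_constant


def reflex_update(map_filtered, setpoint, gain_hr, gain_emax, gain_res,
                  limit_lo=0.5, limit_hi=2.0):
    """Actuator multipliers (m_hr, m_emax, m_res) from the sensed pressure.

    A pressure below the setpoint raises heart rate and contractility and
    constricts the systemic resistance vessels; each multiplier is clipped to
    [limit_lo, limit_hi].
    """
    err = setpoint - map_filtered
    m_hr = np.clip(1.0 + gain_hr * err, limit_lo, limit_hi)
    m_emax = np.clip(1.0 + gain_emax * err, limit_lo, limit_hi)
    m_res = np.clip(1.0 + gain_res * err, limit_lo, limit_hi)
    return m_hr, m_emax, m_res
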