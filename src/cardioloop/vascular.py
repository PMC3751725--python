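"""Vascular segment properties.

Every vascular compartment is a nonlinear Windkessel element whose base
resistance, inertance and elastance follow from the geometry of a single
vessel (length, radius at normal mean pressure, wall thickness) and the
number of parallel vessels lumped into the compartment.  Properties are
re-evaluated each solver step from the current volume, and a viscoelastic
wall resistance in series with the compliance damps the flow pulse without
adding to the total peripheral resistance.
"""

from __future__ import annotations

import numpy as np

from cardioloop.units import MMHG_TO_CGS

__all__ = [
    "base_resistance",
    "base_inertance",
    "base_elastance",
    "reference_volume",
    "transmural_pressure",
    "update_segment_properties",
    "wall_damping",
    "geometry_from_targets",
]


def base_resistance(eta, length, r0, n):
    """Poiseuille resistance at normal mean pressure, mmHg*s/ml.

    ``R0 = 8 eta l / (pi r0^4 n)`` with viscosity already in mmHg*s.
    """
    return 8.0 * eta * length / (np.pi * r0 ** 4 * n)


def base_inertance(rho, length, r0, n):
    """Blood inertance at normal mean pressure, mmHg*s^2/ml.

    ``I0 = rho l / (pi r0^2 n)`` in CGS, converted to mmHg units.
    """
    return rho * length / (np.pi * r0 ** 2 * n) / MMHG_TO_CGS


def base_elastance(y_inc, h, r0, length, n):
    """Volume elastance at normal mean pressure, mmHg/ml.

    ``E0 = Y_inc h / (2 pi r0^3 l n)`` with the Young's modulus in mmHg.
    """
    return y_inc * h / (2.0 * np.pi * r0 ** 3 * length * n)


def reference_volume(r0, length, n):
    """Blood volume contained at normal mean pressure, ml."""
    return np.pi * r0 ** 2 * length * n


def transmural_pressure(v, v_ref, p0, e0):
    """Exponential transmural pressure-volume relation, mmHg.

    ``p(v) = p0 * exp((e0/p0) * (v - v_ref))`` anchors the curve at the
    normal operating point (``p(v_ref) = p0``, ``dp/dv = e0`` there) and
    stiffens with progressive distension.
    """
    return p0 * np.exp((e0 / p0) * (v - v_ref))


def update_segment_properties(v, v_ref, r_base, i_base, e_base, damping_lambda):
    """Instantaneous (R, I, E, Omega) at the current volume.

    The radius scales as ``r = r0 * sqrt(v/v_ref)`` at constant length and
    thickness, so ``R = R0 (v_ref/v)^2``, ``I = I0 (v_ref/v)`` and
    ``E = E0 (v_ref/v)^(3/2)``.
    """
    if np.any(np.asarray(v) <= 0.0):
        raise FloatingPointError("segment volume collapsed to <= 0; vascular "
                                 "collapse is not modeled")
    w = v / v_ref
    r_now = r_base / (w * w)
    i_now = i_base / w
    e_now = e_base * w ** -1.5
    return r_now, i_now, e_now, wall_damping(i_now, e_now, damping_lambda)


def wall_damping(i_now, e_now, damping_lambda):
    """Viscoelastic wall resistance ``Omega = lambda * sqrt(I * E)``, mmHg*s/ml.

    Equals the classical characteristic impedance sqrt(L/C) scaled by lambda;
    it sits in series with the compliance branch (parallel to the blood
    flow), so the total peripheral resistance is unaffected.
    """
    return damping_lambda * np.sqrt(i_now * e_now)


def geometry_from_targets(volume, resistance, compliance, eta, y_inc, r0=None):
    """Invert Poiseuille/thin-wall relations: hemodynamic targets -> geometry.

    Given a target contained volume (ml), base resistance (mmHg*s/ml) and
    compliance 1/E0 (ml/mmHg), return (length, r0, h, n) such that the
    forward formulas reproduce the targets exactly.  If ``r0`` is given the
    vessel count ``n`` may be fractional (a lumped bed); otherwise a single
    vessel (n = 1) is assumed and the radius follows from the targets.
    """
    e0 = 1.0 / compliance
    if r0 is None:
        length = (resistance * volume ** 2 / (8.0 * np.pi * eta)) ** (1.0 / 3.0)
        r0 = np.sqrt(volume / (np.pi * length))
        n = 1.0
    else:
        length = r0 * np.sqrt(resistance * volume / (8.0 * eta))
        n = volume / (np.pi * r0 ** 2 * length)
    h = 2.0 * r0 * volume * e0 / y_inc
    return length, r0, h, n
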