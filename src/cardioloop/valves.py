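"""Heart valves and orifice shunts.

Valves are gradually opening/closing orifices whose pressure gradient is a
Bernoulli resistance plus an inertial term; the inflow length entering the
inertance equals the instantaneous valve diameter.  Septal defects and a
patent ductus follow the Gorlin orifice relation.
"""

from __future__ import annotations

import numpy as np

from cardioloop.units import GRAVITY, MMHG_TO_CGS

__all__ = [
    "effective_area",
    "valve_inertance",
    "valve_gradient",
    "update_valve_opening",
    "shunt_flow",
]

#: floor on the effective orifice area (cm^2) of a nominally closed valve;
#: keeps the flow equation well-posed while making leak flow negligible
AREA_FLOOR = 1e-3


def effective_area(a_min, a_max, zeta):
    """Instantaneous orifice area from the open fraction zeta in [0, 1]."""
    return a_min + (a_max - a_min) * zeta


def valve_inertance(a_eff, rho):
    """Blood inertance of a valve orifice, mmHg*s^2/ml.

    With the inflow length set to the instantaneous diameter,
    ``L = rho * l / A = 2 * rho / (pi * r)`` in CGS, converted to mmHg units.
    """
    if a_eff <= 0.0:
        raise ValueError("a_eff must be positive; a closed valve branch is "
                         "handled by the area floor, not by L(0)")
    r = np.sqrt(a_eff / np.pi)
    return (2.0 * rho / (np.pi * r)) / MMHG_TO_CGS


def valve_gradient(q, dq_dt, a_eff, rho):
    """Pressure drop across a valve, mmHg.

    Bernoulli term ``rho/(2 A^2) * q|q|`` (odd in q) plus the inertial term
    ``L(A) * dq/dt``; both converted from CGS to mmHg.
    """
    if a_eff <= 0.0:
        raise ValueError("a_eff must be positive")
    bernoulli = rho / (2.0 * a_eff * a_eff) * q * abs(q) / MMHG_TO_CGS
    return bernoulli + valve_inertance(a_eff, rho) * dq_dt


def update_valve_opening(zeta, dp_across, dt, k_open, k_close):
    """Advance the open fraction by the pressure-driven first-order rate law.

    ``dzeta/dt = k_open * dp * (1 - zeta)`` for a forward gradient and
    ``k_close * dp * zeta`` for a reversed one; the result is clamped
    to [0, 1].
    """
    if dp_across >= 0.0:
        rate = k_open * dp_across * (1.0 - zeta)
    else:
        rate = k_close * dp_across * zeta
    return min(1.0, max(0.0, zeta + dt * rate))


def shunt_flow(area, dp, gorlin_c=1.0, g=GRAVITY):
    """Bidirectional Gorlin orifice flow, ml/s.

    ``Q = C * A * sqrt(2 g |dP|) * sign(dP)``; with g = 980 cm/s^2 the
    coefficient is 44.3 for area in cm^2 and pressure in mmHg.
    """
    if area < 0.0:
        raise ValueError("area must be non-negative")
    coeff = np.sqrt(2.0 * g)
    return gorlin_c * coeff * area * np.sqrt(abs(dp)) * np.sign(dp)
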