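"""Convective oxygen transport.

Saturation is the transported state; oxygen content follows from
``C = 0.0000136 * Hb * Sat * Volume`` with Hb in g/l and Sat in percent
(the reading that reproduces ~180 ml O2 per litre of arterial blood).
Compartments are perfectly mixed: each exports at its own saturation and
imports at the donor's.  Pulmonary oxygenation raises the non-shunted
fraction of capillary inflow to the alveolar saturation; systemic and
myocardial consumption remove oxygen from the capillary compartments.
"""

from __future__ import annotations

import numpy as np

from cardioloop.units import O2_BINDING

__all__ = [
    "o2_content",
    "advect",
    "pulmonary_oxygenation",
    "myocardial_vo2",
    "consume_systemic",
]


def o2_content(hb, sat, volume):
    """Oxygen content of a compartment, ml O2 (Hb g/l, Sat %, volume ml)."""
    return O2_BINDING * hb * sat * volume


def advect(sat, volumes, branches, flows, hb, dt):
    """One explicit upwind convection step over the compartment graph.

    ``branches`` is an (nb, 2) int array of (upstream, downstream) compartment
    indices and ``flows`` the signed flow (ml/s) of each branch.  Each
    compartment exports oxygen at its own saturation and receives it at the
    donor compartment's saturation; total oxygen is conserved exactly.
    Returns the new saturations for the *same* volumes (volume changes are
    bookkept by the caller, which re-derives saturation from content).
    """
    sat = np.asarray(sat, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    k = O2_BINDING * hb
    content = k * sat * volumes
    for b in range(len(flows)):
        q = flows[b]
        up, dn = branches[b]
        donor = up if q > 0.0 else dn
        moved = q * dt * k * sat[donor]
        content[up] -= moved
        content[dn] += moved
    return content / (k * volumes)


def pulmonary_oxygenation(sat_in, shunt_fraction, alveolar_sat=99.4):
    """Flow-weighted mixed saturation leaving the pulmonary capillaries.

    The non-shunted fraction equilibrates to the alveolar saturation while
    the shunted fraction keeps the incoming (mixed venous) saturation.
    """
    if not 0.0 <= shunt_fraction <= 1.0:
        raise ValueError("shunt_fraction must be within [0, 1]")
    return (1.0 - shunt_fraction) * alveolar_sat + shunt_fraction * sat_in


def myocardial_vo2(pva, e_es, heart_rate, a=1.8e-5, b=0.0024, c=0.014,
                   mass_factor=1.0):
    """Ventricular oxygen consumption from the pressure-volume area, ml O2/min.

    ``VO2_beat = a * PVA + (b * E_es + c) * mass_factor`` per beat, scaled by
    the heart rate.  PVA is stroke work plus the end-systolic potential
    energy in mmHg*ml; a, b, c default to literature values per 100 g of
    myocardium with ``mass_factor`` = mass/100 g.
    """
    per_beat = a * pva + (b * e_es + c) * mass_factor
    return per_beat * heart_rate


def consume_systemic(sat, volumes, vo2_ml_per_min, compartments, weights,
                     hb, dt):
    """Remove systemic oxygen consumption from capillary compartments.

    ``weights`` (summing to 1, typically flow-proportional) distribute the
    sink over ``compartments``.  Saturations are floored at zero; the second
    return value flags whether the floor was hit (supply-limited uptake).
    """
    sat = np.array(sat, dtype=float)
    k = O2_BINDING * hb
    starved = False
    rate = vo2_ml_per_min / 60.0
    for idx, w in zip(compartments, weights):
        removed = w * rate * dt
        content = k * sat[idx] * volumes[idx] - removed
        if content < 0.0:
            content = 0.0
            starved = True
        sat[idx] = content / (k * volumes[idx])
    return sat, starved
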