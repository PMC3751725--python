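"""Unit conventions and conversion constants.

The working unit system is clinical: pressures in mmHg, volumes in ml
(= cm**3), flows in ml/s, time in s, elastances in mmHg/ml.  Vessel and
valve geometry is given in cm, blood density in g/cm**3 and viscosity in
mmHg*s.  Quantities whose natural derivation is CGS (inertances, Bernoulli
pressure drops) are converted with 1 mmHg = 1333.22 dyn/cm**2.
"""

#: dyn/cm**2 per mmHg (= 1333.22 g cm**-1 s**-2)
MMHG_TO_CGS = 1333.22

#: ml O2 bound per (g/l Hb) per (% saturation) per ml blood
O2_BINDING = 0.0000136

#: gravitational acceleration used in the Gorlin orifice formula, cm/s**2
GRAVITY = 980.0

#: Gorlin coefficient 44.3 = sqrt(2 * 980) with the conventional units
#: (area cm**2, pressure mmHg, flow ml/s)
def gorlin_coefficient(g: float = GRAVITY) -> float:
    return (2.0 * g) ** 0.5
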