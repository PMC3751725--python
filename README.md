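# cardioloop

A closed-loop, distributed lumped-parameter (0D) simulator of human
cardiovascular hemodynamics and oxygen transport.

The model comprises:

* **Four cardiac chambers** driven by normalized double-Hill time-varying
  elastance waveforms, with load-dependent contractility roll-off
  (Starling), nonlinear passive diastolic curves (including diastolic
  suction below the passive zero-crossing volume), viscous wall and outflow
  resistances, and independently adjustable activation timing (AV/VV
  delays, rate-dependent scaling of the timing constants with the square
  root of the rate factor).
* **Pressure-transmission septa** between the atria and between the
  ventricles (ventricular septal stiffness scales with the instantaneous
  left ventricular elastance) and an **exponential pericardium** whose
  minimum pressure may be negative.
* **Dynamic heart valves**: Bernoulli + inertance pressure gradients with
  the inflow length equal to the instantaneous orifice diameter, and
  pressure-gradient-driven gradual opening/closing.  Minimum/maximum areas
  model regurgitation and stenosis.
* **A 26-segment vascular network** (systemic, upper-body, pulmonary and
  coronary beds) in which each segment's resistance, inertance and
  elastance follow from vessel geometry (Poiseuille / thin-wall relations)
  and are re-evaluated from the instantaneous volume each step; a
  viscoelastic wall resistance `Omega = lambda*sqrt(L*E)` in series with
  each compliance damps the flow pulse without adding to the peripheral
  resistance.  Transmural pressure follows an anchored exponential
  pressure-volume relation.  Coronary microvessels are compressed by their
  ventricle's pressure, reproducing the systolic reduction of left
  coronary flow.
* **Gorlin orifice shunts** (ASD, VSD, PDA; `Q = 44.3*A*sqrt(dP)`).
* **Convective oxygen transport** (content = 0.0000136*Hb*Sat*Volume) with
  pulmonary oxygenation, an adjustable pulmonary shunt fraction, a fixed
  systemic consumption and beat-by-beat myocardial consumption from the
  ventricular pressure-volume area.
* **An optional baroreflex** adjusting heart rate, ventricular maximum
  elastance and systemic arteriolar resistance from the filtered mean
  arterial pressure.

The 68 differential states (30 compartment volumes, 34 branch flows, 4
valve open fractions) are advanced by implicit Euler at a 0.25 ms step
with a modified-Newton solver (lazily refreshed finite-difference
Jacobian) compiled with numba; valve fractions are advanced by their exact
one-step exponential update.  Blood volume is conserved to round-off.

## Presets and scenarios

`cardioloop.parameters.load_preset(name)` loads the calibrated baseline
adult (blood volume 5600 ml, HR 72 min^-1, Hb 140 g/l, VO2 250 ml/min,
pulmonary capillary saturation 99.4 %, 10 % pulmonary shunt, Young's
modulus 3000 mmHg, lambda 0.5) or a scenario applied on top of it:
`systolic_hf`, `diastolic_hf`, `aortic_stenosis`, `aortic_regurgitation`,
`valsalva`, `valsalva_reflex`, `exercise`, `arteriosclerosis`.  Scenario
files are plain JSON patch documents; vascular dimensions in the baseline
are reconstructed from standard adult anatomy or calibrated against the
published normal-physiology table (see `provenance` per segment, and
`src/cardioloop/presets/_build.py` which regenerates the preset files from
the hemodynamic working points).

## Command line

```bash
cardioloop run --preset normal --duration 60 --out trace.csv
cardioloop scenario aortic_stenosis
cardioloop metrics trace.csv
cardioloop sensitivity --params-file params.txt --out sens.csv
cardioloop presets
```

Traces are CSV, one row per sample, one column per signal (pressures mmHg,
volumes ml, flows ml/s, saturations %), with a unit header comment.

## Library use

```python
from cardioloop import load_preset, run, beat_metrics

trace = run(load_preset("normal"), duration=60.0)
print(beat_metrics(trace).iloc[-1][["co", "ef", "sv", "svo2"]])
```

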