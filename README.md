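# fhposture

Digitized assessment of **forward head posture (FHP)** from a two-sensor
wearable: a resistive flex sensor at the back of the neck and a three-axis
accelerometer worn at the ear.

FHP — the head resting anterior to the shoulder line instead of vertically
above it — is normally judged by a clinician with sliding callipers (anterior
ear–shoulder displacement) or from the craniovertebral (CV) angle on a
photograph. `fhposture` implements a sensor-based, reproducible version of
both criteria plus a vector-sum posture model, for engineers and researchers
prototyping posture-monitoring devices:

* **Calibration** — per-channel voltage↔angle maps from a bench table
  (piecewise-linear interpolant, exact at every node, plus an OLS affine
  summary; the response is close to linear at ≈ 9–12 mV/degree).
* **Displacement** — anterior head displacement `d` by double integration of
  the ear-worn accelerometer's anterior axis,
  `d(t) = ∬ a(τ) dτ²`, with gravity/bias removal and zero-velocity-update
  (ZUPT) drift suppression anchored on detected stationary intervals.
* **Severity** — calliper-style bands: `d < 1 cm` none, `1–2.5 cm` slight,
  `2.5–5 cm` severe, `≥ 5 cm` highly severe (lower bounds inclusive).
* **Vector model** — neck angle `θ₁` (flex sensor) and head angle `θ₂`
  (gravity tilt) each tilt a unit segment vector from vertical; the
  renormalised sum `v = (n(θ₁) + h(θ₂)) / ‖·‖`, anchored at C1, must stay
  inside a 36°-wide normal cone (±18° sagittal by default).
* **CV screen** — FHP flagged when the CV angle is strictly below 45°
  (proxy `CV ≈ 90° − θ₁` until a validated conversion exists).
* **Load model** — effective head load `m(d) = m₀ + 0.45 kg · d / 2.5 cm`
  (base mass `m₀ = 5 kg`) and neck moment `M = m(d) · g · d`.
* **Simulator** — scripted head motions (smoothstep easing) rendered into
  noisy sensor voltages through the same calibration, so the whole chain is
  testable without hardware.

## Worked example

Recover displacement from a simulated noisy recording
(`examples/02_displacement_from_motion.py`):

```text
3 cm out and back: net +0.126 cm, peak excursion 3.043 cm, severity none
3 cm one-way lean: net +3.039 cm, peak excursion 3.043 cm, severity severe
```

A movement that returns to its starting point integrates back to ≈ 0 net
displacement (the standard sanity check of an inertial chain), while a
genuine 3 cm forward lean is recovered within ~1% and classified *severe*.
The full assessment of an FHP onset (3 cm forward slide with 50° neck
flexion, `examples/04_full_assessment.py`) prints:

```text
severity severe: the 3.1 cm forward shift raises the effective head load
to 5.55 kg (moment 1.67 N*m about the cervical pivot)
```

with the CV screen flagged (40.0° < 45°) and the posture vector 25.0°
outside the 36° cone — the three parallel criteria agreeing on faulty
posture.

## Command line

```bash
fhp calibrate                        # inspect the bundled calibration table
echo '{"kind": "return_trip", "distance_cm": 3}' > script.json
fhp simulate --script script.json --seed 1 --out log.csv
fhp analyze --log log.csv --out report.json
fhp report --report report.json
```

## Layout

```
src/fhposture/    calibration, kinematics, vector_model, assessment,
                  simulator, config, io, pipeline, cli
examples/         one narrative script per capability
tests/            pytest suite (unit, property and acceptance tests)
docs/methods.md   models, assumptions, parameter choices, limitations
```
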