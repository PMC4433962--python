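# Methods

This note records the models implemented in `fhposture`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
experiments do and do not demonstrate.

## Sensors and calibration

Two channels characterise posture: a resistive flex sensor along the back of
the neck (bridge output voltage rises with flexion) and a three-axis
accelerometer at the ear. Both are calibrated on the bench by recording the
output voltage at known angles from −60° to +60° in 10° steps; the bundled
table (`data/voltage_angle_table.csv`) holds one such characterisation for
four channels (`flex, x, y, z`).

Two fits are kept per channel:

* a **piecewise-linear interpolant** through all 13 nodes — exact at the
  nodes and strictly monotone, used as the default conversion;
* an **OLS affine fit** (slope ≈ 8.9 mV/° for the flex channel,
  ≈ 12 mV/° for the accelerometer axes; residual RMS 22–37 mV) — a
  near-linearity summary, and the extension used when extrapolation beyond
  ±60° is explicitly enabled.

Channel-to-column assignment is configuration (`PipelineConfig.channel_map`),
so a different wiring order needs no code change.

The accelerometer columns are read as per-axis tilt calibrations under a
common protocol (each axis rotated from −60° to +60° relative to
horizontal), i.e. `v(θ) ≈ v₀ + s·g·sin θ` with `v₀` the zero-g offset (the
0° node) and `s` the gain in mV/(m/s²). The default gain is derived from
the x column's affine slope, `s = slope·180/(π·g) ≈ 67 mV/(m/s²)`, the value
that makes the printed voltage-per-degree slope consistent with gravity
projection. It is configurable (`SimulationConfig.sensitivity`,
`PipelineConfig.sensitivity`).

## Displacement by double integration

Anterior head displacement is the double time-integral of the anterior-axis
specific force after removing gravity and bias. Double integration amplifies
low-frequency error: a constant bias grows as `t²` and white sensor noise
integrates into a random walk whose displacement error grows as `t^{3/2}`.
The chain therefore is:

1. affine voltage→acceleration conversion, `a = (v − v₀)/s`;
2. trapezoidal cumulative integration with zero initial velocity/position;
3. drift suppression (`detrend` mode):
   * `none` — raw double integration (used for closed-form verification);
   * `linear` — best-fit line removed after each integration stage. This
     suppresses drift for motions known to return to the start, but an OLS
     line through a monotone ramp removes most of its net, so it **nulls
     genuine one-way displacement** (measured: a clean 3 cm one-way move
     integrates to ≈ −1.3 cm in this mode). Provided for completeness, not
     used by the pipeline;
   * `zupt` (default) — zero-velocity updates. Stationary intervals are
     detected (below) and the integrated velocity is anchored to zero across
     every stationary run, with the correction between runs being the
     straight line through the velocity values at the adjacent run edges.
     Because integrated noise is *observed directly* at those edge samples,
     the only residual error over a movement gap of duration `G` is a
     Brownian-bridge integral with standard deviation
     `σ_a·G^{3/2}/√(12·f_s)` — about 0.07 cm for the default conditions
     (σ_a ≈ 0.03 m/s², G ≈ 0.9 s, f_s = 100 Hz). This preserves one-way
     nets exactly in the noise-free limit.

**Stationarity detection.** The per-sample noise level `σ_a` is estimated
robustly from first differences of the acceleration
(`median|Δa|/(√2·0.6745)`), which ordinary head-motion jerk barely affects.
The acceleration is integrated once and detrended by the line through its
endpoints (records are assumed to start and end at rest, so this absorbs
constant bias); under pure noise the result is a Brownian bridge with
maximum standard deviation `σ_v = σ_a·√(T/4f_s)`. Samples whose detrended
velocity exceeds `3·σ_v` (floor 2·10⁻⁴ m/s, so noise-free records still
split correctly) are flagged as moving and the moving mask is dilated by
0.15 s to cover the low-velocity tails of each movement. Detection SNR for
the smallest scripted movement (0.5 cm over 0.6 s: peak velocity
12.5 mm/s vs σ_v ≈ 2 mm/s) is ≈ 6.

**Filters.** A zero-phase 4th-order Butterworth high-pass (0.2 Hz default)
implements gravity/bias DC rejection as a standalone operation, and a
10 Hz low-pass is available for readout denoising and event detection. The
displacement chain itself does not low-pass: the integration error budget is
set by the noise spectrum near DC, which a low-pass does not touch (and the
ZUPT bridge handles), while the high-pass would distort one-way nets. Both
filters remain useful for display, direction detection and DC-rejection
checks.

**Direction of movement.** Movement bursts are found by thresholding |a|
(bursts separated by gaps < 0.3 s are merged so one biphasic
accelerate–decelerate pulse is a single event); the sign of the first
supra-threshold excursion gives the direction — rising edge first means
forward, falling edge first backward. Negating a trace flips every event.

## Posture model

* **Head tilt from gravity** (quasi-static only; rejected if |g| deviates
  more than 20% from 9.81 m/s²): standard pitch/roll formulas
  `sagittal = atan2(g_x, g_z)`, `coronal = atan2(g_y, √(g_x²+g_z²))`, the
  exact inverse of the segment parametrisation below.
* **Segment vectors**: a segment tilted `s` sagittally and `c` coronally
  points along `(sin s·cos c, sin c, cos s·cos c)` in (anterior, lateral,
  vertical) axes — unit norm for any angles.
* **Vector sum**: posture vector `v = (w₁·n(θ₁) + w₂·h(θ₂,c)) / ‖·‖`,
  anchored at C1. The weighting of the two segments is not physiologically
  determined; equal unit weights are the default and per-segment weights are
  exposed for future calibration. Equal tilts compose to the same tilt, so
  the model reduces sensibly in the degenerate case.
* **Normal cone**: total width 36°, split symmetrically ±18° by default. The
  forward/backward split is a free choice (clinically a smaller forward
  tolerance may be appropriate); it is configurable with the constraint
  `forward + backward = width`. Classification uses the *signed sagittal*
  deviation `atan2(v_ant, v_vert)` with inclusive boundaries, so it is
  monotone: any smaller same-sign deviation of an inside vector is inside.
* **CV angle**: no validated conversion from the neck angle exists, so the
  screen uses the proxy `CV = 90° − θ₁` (clipped to [0°, 90°]), exposed as a
  configurable affine map. The flag is strict: `CV < 45°`.

## Severity and load

Severity bands on displacement are lower-inclusive, with the unlabeled
`[0, 1) cm` region assigned *none*: `[1, 2.5)` slight, `[2.5, 5)` severe,
`[5, ∞)` highly severe; all three boundaries are configurable. The load rule
(+0.45 kg per 2.5 cm) is read as continuous-linear, 0.18 kg/cm over the
5.0 kg base head mass (midpoint of the typical 4.5–5.5 kg adult range); a
staircase mode (whole 2.5 cm steps only) exists for cross-checking. Neck
moment is `m(d)·g·(d/100)` N·m with `d` in cm. The displacement-severity
and vector-cone criteria are deliberately reported side by side, not fused.

## Simulator

Motion scripts are ordered segments easing displacement and/or angles to
absolute targets with the C¹ smoothstep `3u²−2u³` (continuous velocity,
bounded acceleration — a deliberate, smooth head reposition rather than an
impact). Defaults: 0.6 s per movement, 0.5 s lead-in/tail rest, 0.6 s dwell,
100 Hz sampling, 2 mV additive i.i.d. Gaussian noise per channel. Voltages:
accelerometer = zero-g offset + gain × (motion acceleration + gravity
projection of the instantaneous head tilt); flex = calibrated voltage at the
instantaneous neck angle. Identical seeds give bit-identical traces. An
optional random-walk bias is intentionally absent by default; noise is the
only stochastic element.

What the simulator does *not* emulate: gyroscopes (the hardware has none),
vertical/lateral translation, sensor placement error, skin-motion artefact,
temperature drift, or correlated electronic noise. Passing tests therefore
demonstrate the correctness and noise robustness of the processing chain
under additive white noise — not clinical validity on human recordings.

## Scope and limitations

* **Constant-orientation assumption.** Displacement is recovered from a
  single horizontal axis, so a head-tilt change during the record shifts the
  gravity baseline and masquerades as acceleration; accelerometer-only
  hardware cannot separate the two. The pipeline compares the gravity
  baseline between the first and last rest periods and marks
  `displacement_reliable: false` (with a warning) when the orientation moved
  more than ≈ 3°. Neck-angle changes are harmless (the flex channel does not
  couple into the accelerometer).
* **Posture angles** are taken from the final stationary interval of the
  record (falling back to the last 0.2 s), so a record must end at rest for
  a meaningful angle assessment.
* **Experiment sizes.** The bundled experiments use short records (1.6–3.1 s,
  160–310 samples) and modest replication (20 seeds for the zero-return
  check; 8 trials averaged per distance on the 0.5–5 cm grid), which a
  laptop reruns in seconds; the distance-grid protocol reports per-distance
  trial means, standard practice for a stochastic estimator whose
  single-trial error (≈ 0.07 cm) is material only for the smallest
  distances.
* **Electronics out of scope**: bridge circuits, resistance-to-voltage
  conversion, analogue filter design, and the electrical-stimulation
  feedback side of a corrective device are not modelled.
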