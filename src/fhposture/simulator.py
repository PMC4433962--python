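"""Synthetic head-motion scenarios and the sensor voltages they produce.

No public dataset of neck-worn flex + ear-worn accelerometer recordings
exists, so every pipeline stage is exercised against this simulator.  A
:class:`MotionScript` is an ordered list of segments, each easing the
anterior displacement and/or the posture angles from their previous values
to new targets with a smoothstep profile (C1 trajectories: velocity is
continuous, acceleration bounded).  :func:`simulate_motion` samples the
ground-truth kinematics analytically; :func:`synthesize_voltages` maps them
through the calibration into noisy sensor voltages:

* accelerometer channel = zero-g offset + sensitivity * (motion component +
  gravity projection for the instantaneous head tilt) + Gaussian noise,
* flex channel = calibrated voltage at the instantaneous neck angle + noise.

The default conditions are an adult seated still, making deliberate head
repositions of a few cm over ~0.6 s, sampled at 100 Hz with 2 mV RMS
additive noise.  Identical seeds give bit-identical traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import (
    CalibrationTable,
    angle_to_voltage,
    fit_channel_calibration,
)
from .kinematics import SignalTrace
from .vector_model import STANDARD_GRAVITY, segment_vector

__all__ = [
    "Segment",
    "MotionScript",
    "SimulationConfig",
    "GroundTruth",
    "simulate_motion",
    "synthesize_voltages",
    "make_one_way_script",
    "make_return_trip_script",
    "sensitivity_from_calibration",
]

DEFAULT_MOVE_S = 0.6  # deliberate head reposition duration
DEFAULT_REST_S = 0.5  # lead-in / tail rest


@dataclass(frozen=True)
class Segment:
    """One script segment: ease to the given absolute targets over
    ``duration`` seconds.  ``None`` targets hold the previous value."""

    duration: float
    displacement_cm: float | None = None
    neck_angle: float | None = None
    head_angle: float | None = None
    coronal_tilt: float | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class MotionScript:
    """Ordered segments; all quantities start from zero (upright, at rest)."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segments = tuple(self.segments)
        object.__setattr__(self, "segments", segments)
        if not segments:
            raise ValueError("motion script has no segments")

    @property
    def duration(self) -> float:
        return sum(seg.duration for seg in self.segments)

    def final_displacement(self) -> float:
        out = 0.0
        for seg in self.segments:
            if seg.displacement_cm is not None:
                out = seg.displacement_cm
        return out


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling and noise conditions for voltage synthesis.

    ``sensitivity`` is the accelerometer gain in mV per m/s^2; ``None``
    derives it from the calibration table's x column (the gain that makes
    the printed voltage-vs-tilt slope consistent with gravity projection).
    """

    rate: float = 100.0  # Hz
    noise_mv: float = 2.0  # additive Gaussian sigma, mV
    seed: int = 0
    sensitivity: float | None = None
    gravity: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.noise_mv < 0:
            raise ValueError("noise sigma must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic trajectories on a shared uniform time base."""

    times: np.ndarray
    displacement_cm: np.ndarray
    velocity: np.ndarray  # m/s
    acceleration: np.ndarray  # m/s^2
    neck_angle: np.ndarray  # degrees
    head_angle: np.ndarray
    coronal_tilt: np.ndarray
    rate: float


def _smoothstep(u: np.ndarray) -> np.ndarray:
    return 3.0 * u**2 - 2.0 * u**3


def _smoothstep_d1(u: np.ndarray) -> np.ndarray:
    return 6.0 * u * (1.0 - u)


def _smoothstep_d2(u: np.ndarray) -> np.ndarray:
    return 6.0 - 12.0 * u


def simulate_motion(script: MotionScript, cfg: SimulationConfig) -> GroundTruth:
    """Sample the script's ground-truth kinematics at ``cfg.rate``.

    Displacement, velocity and acceleration are evaluated analytically from
    the smoothstep easing, so velocity is exactly the derivative of
    displacement and acceleration of velocity (up to the closed forms).
    """
    n = int(round(script.duration * cfg.rate)) + 1
    t = np.arange(n) / cfg.rate
    disp = np.zeros(n)
    vel = np.zeros(n)
    acc = np.zeros(n)
    angles = {"neck_angle": np.zeros(n), "head_angle": np.zeros(n),
              "coronal_tilt": np.zeros(n)}

    start = 0.0
    cur_disp = 0.0
    cur_ang = {k: 0.0 for k in angles}
    for seg in script.segments:
        end = start + seg.duration
        sel = (t >= start) & (t <= end)
        u = (t[sel] - start) / seg.duration
        if seg.displacement_cm is not None:
            delta_m = (seg.displacement_cm - cur_disp) / 100.0
            disp[sel] = cur_disp + (seg.displacement_cm - cur_disp) * _smoothstep(u)
            vel[sel] = delta_m * _smoothstep_d1(u) / seg.duration
            acc[sel] = delta_m * _smoothstep_d2(u) / seg.duration**2
            cur_disp = seg.displacement_cm
        else:
            disp[sel] = cur_disp
            vel[sel] = 0.0
            acc[sel] = 0.0
        for key, arr in angles.items():
            target = getattr(seg, key)
            if target is not None:
                arr[sel] = cur_ang[key] + (target - cur_ang[key]) * _smoothstep(u)
                cur_ang[key] = target
            else:
                arr[sel] = cur_ang[key]
        after = t > end
        disp[after] = cur_disp
        for key, arr in angles.items():
            arr[after] = cur_ang[key]
        start = end

    return GroundTruth(
        times=t,
        displacement_cm=disp,
        velocity=vel,
        acceleration=acc,
        neck_angle=angles["neck_angle"],
        head_angle=angles["head_angle"],
        coronal_tilt=angles["coronal_tilt"],
        rate=cfg.rate,
    )


def sensitivity_from_calibration(
    table: CalibrationTable, channel: str = "x", gravity: float = STANDARD_GRAVITY
) -> float:
    """Accelerometer gain (mV per m/s^2) implied by a tilt-calibration column.

    Near upright a tilt of one degree changes the gravity projection on a
    horizontal axis by ``g * pi / 180`` m/s^2, so the affine slope in mV/deg
    divides out to a gain in mV/(m/s^2).
    """
    cal = fit_channel_calibration(table, channel)
    return cal.slope * 180.0 / (np.pi * gravity)


def synthesize_voltages(
    truth: GroundTruth,
    cfg: SimulationConfig,
    table: CalibrationTable,
) -> dict[str, SignalTrace]:
    """Noisy sensor voltages (mV) for the ground-truth motion.

    Returns traces keyed ``vx, vy, vz, vflex``.  Accelerometer axes see the
    gravity projection of the instantaneous head tilt plus (on the anterior
    axis) the motion acceleration; the flex channel follows the calibrated
    neck-angle map.  Gaussian noise with ``cfg.noise_mv`` RMS is added from a
    generator seeded by ``cfg.seed`` — identical configs give identical
    bytes.
    """
    for ch in ("flex", "x", "y", "z"):
        if ch not in table.channels:
            raise ValueError(f"calibration table lacks channel {ch!r}")
    flex_cal = fit_channel_calibration(table, "flex")
    lo, hi = flex_cal.degree_range
    if truth.neck_angle.min() < lo or truth.neck_angle.max() > hi:
        raise ValueError("scripted neck angle leaves the calibrated range")
    sens = cfg.sensitivity
    if sens is None:
        sens = sensitivity_from_calibration(table, gravity=cfg.gravity)

    # gravity in device axes for the instantaneous head orientation
    g_dir = np.stack(
        [segment_vector(s, c) for s, c in zip(truth.head_angle, truth.coronal_tilt)]
    )
    g_axes = cfg.gravity * g_dir  # columns: anterior, lateral, vertical
    ax = truth.acceleration + g_axes[:, 0]
    ay = g_axes[:, 1]
    az = g_axes[:, 2]

    offsets = {
        ch: float(angle_to_voltage(fit_channel_calibration(table, ch), 0.0))
        for ch in ("x", "y", "z")
    }
    vflex_clean = angle_to_voltage(flex_cal, truth.neck_angle)

    rng = np.random.default_rng(cfg.seed)
    n = truth.times.size
    channels = {
        "vx": offsets["x"] + sens * ax,
        "vy": offsets["y"] + sens * ay,
        "vz": offsets["z"] + sens * az,
        "vflex": np.asarray(vflex_clean, dtype=float),
    }
    out = {}
    for label, clean in channels.items():
        noise = rng.normal(0.0, cfg.noise_mv, n) if cfg.noise_mv > 0 else 0.0
        out[label] = SignalTrace(
            values=clean + noise, rate=cfg.rate, label=label, units="mV"
        )
    return out


def make_one_way_script(
    distance_cm: float,
    move_s: float = DEFAULT_MOVE_S,
    lead_s: float = DEFAULT_REST_S,
    tail_s: float = DEFAULT_REST_S,
) -> MotionScript:
    """Rest, move forward by ``distance_cm``, rest."""
    if distance_cm <= 0:
        raise ValueError("distance must be positive")
    return MotionScript(
        segments=(
            Segment(duration=lead_s),
            Segment(duration=move_s, displacement_cm=distance_cm),
            Segment(duration=tail_s),
        )
    )


def make_return_trip_script(
    distance_cm: float,
    dwell_s: float = DEFAULT_MOVE_S,
    move_s: float = DEFAULT_MOVE_S,
    lead_s: float = DEFAULT_REST_S,
    tail_s: float = DEFAULT_REST_S,
) -> MotionScript:
    """Out-dwell-back script with zero net displacement by construction."""
    if distance_cm <= 0:
        raise ValueError("distance must be positive")
    return MotionScript(
        segments=(
            Segment(duration=lead_s),
            Segment(duration=move_s, displacement_cm=distance_cm),
            Segment(duration=dwell_s),
            Segment(duration=move_s, displacement_cm=0.0),
            Segment(duration=tail_s),
        )
    )
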