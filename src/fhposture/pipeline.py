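"""End-to-end analysis: sensor log -> calibrated signals -> assessment.

``run_pipeline`` ties the stages together: calibration fits, voltage ->
acceleration conversion, stationary-interval detection, drift-suppressed
double integration to anterior displacement, posture angles from the final
quiet interval (gravity tilt for the head, flex voltage for the neck), and
the clinical-style assessment.  Deterministic for fixed inputs; the JSON
report echoes the configuration and software version.
"""

from __future__ import annotations

import logging
from datetime import datetime, timezone

import numpy as np

from . import __version__
from .assessment import FHPAssessment, LoadModel, assess
from .calibration import CalibrationTable, fit_channel_calibration, voltage_to_angle
from .config import PipelineConfig
from .kinematics import (
    SignalTrace,
    acceleration_from_voltage,
    detect_stationary,
    double_integrate,
    lowpass_denoise,
    movement_direction,
)
from .simulator import sensitivity_from_calibration
from .vector_model import AngleState, NormalCone, head_tilt_from_acceleration

__all__ = ["run_pipeline"]

logger = logging.getLogger("fhposture")

MIN_QUIET_S = 0.2  # minimum final quiet window used for posture angles


def _final_quiet_window(stationary: np.ndarray, rate: float) -> slice:
    """Indices of the trailing stationary run, or the last samples if the
    trace never settles."""
    n = stationary.size
    min_len = max(2, int(round(MIN_QUIET_S * rate)))
    if stationary[-1]:
        start = n - 1
        while start > 0 and stationary[start - 1]:
            start -= 1
        if n - start >= min_len:
            return slice(start, n)
    return slice(max(0, n - min_len), n)


def run_pipeline(
    traces: dict[str, SignalTrace],
    table: CalibrationTable,
    config: PipelineConfig | None = None,
) -> tuple[FHPAssessment, dict]:
    """Analyse one sensor log; returns the assessment and a JSON-able report."""
    config = config if config is not None else PipelineConfig()
    cals = {
        role: fit_channel_calibration(table, config.channel(role))
        for role in ("flex", "x", "y", "z")
    }
    sens = config.sensitivity
    if sens is None:
        sens = sensitivity_from_calibration(table, channel=config.channel("x"))

    accel = {
        axis: acceleration_from_voltage(traces[f"v{axis}"], cals[axis], sens)
        for axis in ("x", "y", "z")
    }
    stationary = detect_stationary(accel["x"])
    disp = double_integrate(accel["x"], detrend=config.detrend, stationary=stationary)
    net = disp.net
    logger.info("net displacement %.3f cm (peak %.3f cm)", net, disp.peak_excursion)

    # displacement from a single horizontal axis is only valid while the head
    # orientation stays fixed: a tilt change shifts the gravity baseline and
    # masquerades as acceleration (no gyro is available to separate the two)
    displacement_reliable = True
    idx = np.flatnonzero(stationary)
    if idx.size >= 4:
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        first_mean = float(np.mean(accel["x"].values[runs[0]]))
        last_mean = float(np.mean(accel["x"].values[runs[-1]]))
        if abs(last_mean - first_mean) > 0.5:  # m/s^2, ~3 deg of tilt
            displacement_reliable = False
            logger.warning(
                "gravity baseline moved %.2f m/s^2 between rest periods: head "
                "orientation changed mid-record, displacement estimate is "
                "unreliable", last_mean - first_mean,
            )

    quiet = _final_quiet_window(stationary, accel["x"].rate)
    g_components = [float(np.mean(accel[a].values[quiet])) for a in ("x", "y", "z")]
    head_sag, head_cor = head_tilt_from_acceleration(*g_components)
    flex_mv = float(np.mean(traces["vflex"].values[quiet]))
    neck = float(voltage_to_angle(cals["flex"], flex_mv, extrapolate=True))
    angles = AngleState(
        neck_angle=float(np.clip(neck, -90, 90)),
        head_angle=float(np.clip(head_sag, -90, 90)),
        coronal_tilt=float(np.clip(head_cor, -90, 90)),
    )
    logger.info("angles: neck %.2f deg, head %.2f deg, coronal %.2f deg",
                angles.neck_angle, angles.head_angle, angles.coronal_tilt)

    cone = NormalCone(width=config.cone_width, forward=config.cone_forward)
    model = LoadModel(
        head_mass=config.head_mass,
        increment=config.load_increment,
        step=config.load_step,
    )
    result = assess(
        displacement=max(net, 0.0),
        angles=angles,
        cone=cone,
        model=model,
        cv_threshold=config.cv_threshold,
        severity_bounds=config.severity_bounds,
    )
    logger.info("severity %s; deviation %.2f deg; inside cone %s",
                result.severity.value, result.deviation_deg,
                result.vector_inside_cone)

    smooth = lowpass_denoise(accel["x"], config.lowpass_cutoff, config.filter_order)
    noise = np.median(np.abs(np.diff(accel["x"].values))) / (np.sqrt(2) * 0.6745)
    events = movement_direction(smooth, threshold=max(5.0 * noise, 1e-3))

    report = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "software_version": __version__,
        "net_displacement_cm": net,
        "peak_excursion_cm": disp.peak_excursion,
        "displacement_reliable": displacement_reliable,
        "movement_events": [
            {"onset_s": e.onset_time, "direction": e.direction} for e in events
        ],
        "assessment": result.to_dict(),
        "config_echo": config.to_dict(),
    }
    return result, report
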