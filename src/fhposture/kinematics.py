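"""Acceleration-to-displacement processing for head motion traces.

The anterior head displacement is recovered from an ear-worn accelerometer by
double integration.  Raw double integration is notoriously drift-prone: any
constant offset (gravity leakage, amplifier bias) grows quadratically, and
broadband noise integrates into a random walk.  The chain implemented here:

1. voltage -> specific force via the channel calibration (affine model),
2. optional zero-phase Butterworth filters (high-pass for gravity/bias DC,
   low-pass for readout denoising),
3. trapezoidal double integration with drift suppression.

Drift suppression offers three modes.  ``"none"`` integrates as-is (used for
closed-form checks).  ``"linear"`` removes a best-fit line from the velocity
and position stages — effective when the motion is known to return to its
starting point, but it also nulls the net displacement of a genuine one-way
move, so it is not the default.  ``"zupt"`` (default) applies zero-velocity
updates: stationary intervals are detected from the integrated velocity and
the velocity random walk is anchored to zero across them, which preserves
one-way net displacement while cancelling integration drift.  Stationarity
detection thresholds the endpoint-detrended velocity against the expected
Brownian-bridge excursion of integrated sensor noise, with the noise level
estimated robustly from first differences of the acceleration itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats
from scipy.integrate import cumulative_trapezoid

from .calibration import ChannelCalibration, angle_to_voltage

__all__ = [
    "SignalTrace",
    "DisplacementTrace",
    "MovementEvent",
    "acceleration_from_voltage",
    "remove_gravity_and_drift",
    "lowpass_denoise",
    "detect_stationary",
    "double_integrate",
    "net_displacement",
    "movement_direction",
    "log_linearity_check",
]


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled time series.

    Parameters
    ----------
    values
        Sample values (length >= 2).
    rate
        Sampling rate in Hz (> 0).
    start_time
        Time of the first sample in seconds.
    label, units
        Free-form channel label (e.g. ``"vx"``) and unit string (``"mV"``,
        ``"m/s^2"``, ``"cm"``).
    """

    values: np.ndarray
    rate: float
    start_time: float = 0.0
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        if values.ndim != 1 or values.size < 2:
            raise ValueError("trace needs at least 2 samples")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return (self.values.size - 1) / self.rate


@dataclass(frozen=True)
class DisplacementTrace:
    """Anterior displacement in cm, with net and peak summaries.

    ``net`` is last minus first sample; ``|net| <= peak`` always holds
    (peak is the maximum absolute excursion from the starting position).
    """

    trace: SignalTrace

    def __post_init__(self) -> None:
        if self.trace.units != "cm":
            raise ValueError("displacement trace must be in cm")

    @property
    def net(self) -> float:
        return float(self.trace.values[-1] - self.trace.values[0])

    @property
    def peak_excursion(self) -> float:
        return float(np.max(np.abs(self.trace.values - self.trace.values[0])))


@dataclass(frozen=True)
class MovementEvent:
    """One detected movement burst.

    The sign of the leading acceleration edge carries the direction: a burst
    whose first supra-threshold excursion is positive (rising edge first)
    is forward motion, a negative-first burst is backward.
    """

    onset_time: float
    direction: str  # "forward" | "backward"
    leading_edge: str = field(init=False)

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"bad direction {self.direction!r}")
        object.__setattr__(
            self, "leading_edge", "rising" if self.direction == "forward" else "falling"
        )


def acceleration_from_voltage(
    trace: SignalTrace,
    cal: ChannelCalibration,
    sensitivity: float,
    zero_g_offset: float | None = None,
) -> SignalTrace:
    """Convert an accelerometer voltage trace (mV) to specific force (m/s^2).

    ``a = (v - zero_g_offset) / sensitivity``.  The zero-g offset defaults to
    the calibration's 0-degree node voltage, i.e. the reading when the axis
    is horizontal and sees no gravity component.
    """
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive (mV per m/s^2)")
    if zero_g_offset is None:
        zero_g_offset = float(angle_to_voltage(cal, 0.0))
    return replace(
        trace,
        values=(trace.values - zero_g_offset) / sensitivity,
        units="m/s^2",
    )


def _sos(cutoff: float, rate: float, btype: str, order: int):
    if not 0 < cutoff < rate / 2:
        raise ValueError(
            f"{btype} cutoff {cutoff} Hz must lie in (0, Nyquist={rate / 2} Hz)"
        )
    return signal.butter(order, cutoff, btype=btype, fs=rate, output="sos")


def remove_gravity_and_drift(
    trace: SignalTrace, cutoff: float = 0.2, order: int = 4
) -> SignalTrace:
    """Zero-phase Butterworth high-pass removing the gravity/bias DC component.

    Applied forward-backward (``sosfiltfilt``) so event timing is preserved.
    A constant input maps to (numerically) zero output.
    """
    sos = _sos(cutoff, trace.rate, "highpass", order)
    return replace(trace, values=signal.sosfiltfilt(sos, trace.values))


def lowpass_denoise(
    trace: SignalTrace, cutoff: float = 10.0, order: int = 4
) -> SignalTrace:
    """Zero-phase Butterworth low-pass for readout denoising."""
    sos = _sos(cutoff, trace.rate, "lowpass", order)
    return replace(trace, values=signal.sosfiltfilt(sos, trace.values))


def _dilate(mask: np.ndarray, k: int) -> np.ndarray:
    if k <= 0:
        return mask
    out = mask.copy()
    for s in range(1, k + 1):
        out[s:] |= mask[:-s]
        out[:-s] |= mask[s:]
    return out


def estimate_noise_std(trace: SignalTrace) -> float:
    """Robust per-sample noise std from first differences.

    ``median(|diff|) / (sqrt(2) * 0.6745)`` — insensitive to the slow
    acceleration waveform of ordinary head motion.
    """
    return float(np.median(np.abs(np.diff(trace.values))) / (np.sqrt(2) * 0.6745))


def detect_stationary(
    trace: SignalTrace,
    threshold_sigmas: float = 3.0,
    dilate_s: float = 0.15,
    velocity_floor: float = 2e-4,
) -> np.ndarray:
    """Boolean mask of samples judged stationary (at rest).

    The acceleration is integrated once and detrended by the line through its
    endpoints (the trace is assumed to start and end at rest, so that line
    absorbs any constant bias).  Under pure sensor noise the result is a
    Brownian bridge with maximum std ``sigma_a * sqrt(T / (4 fs))``; samples
    whose detrended velocity exceeds ``threshold_sigmas`` times that (or
    ``velocity_floor`` m/s, whichever is larger) are flagged as moving, the
    moving mask is dilated by ``dilate_s`` seconds to cover the low-velocity
    tails of each movement, and the complement is returned.
    """
    a = trace.values
    n = a.size
    t = np.arange(n) / trace.rate
    total = t[-1]
    sigma_a = estimate_noise_std(trace)
    v = cumulative_trapezoid(a - a.mean(), t, initial=0.0)
    bridge = v - (v[0] + (v[-1] - v[0]) * t / total)
    sigma_v = sigma_a * np.sqrt(total / (4.0 * trace.rate))
    thresh = max(threshold_sigmas * sigma_v, velocity_floor)
    moving = _dilate(np.abs(bridge) > thresh, int(round(dilate_s * trace.rate)))
    return ~moving


def double_integrate(
    trace: SignalTrace,
    detrend: str = "zupt",
    stationary: np.ndarray | None = None,
) -> DisplacementTrace:
    """Integrate acceleration (m/s^2) twice to anterior displacement (cm).

    Cumulative trapezoids with zero initial velocity and position.  See the
    module docstring for the ``detrend`` modes (``"zupt"`` default,
    ``"linear"``, ``"none"``).  With ``"zupt"`` a precomputed ``stationary``
    mask may be supplied; otherwise :func:`detect_stationary` is used.
    """
    if detrend not in ("none", "linear", "zupt"):
        raise ValueError(f"detrend must be 'none', 'linear' or 'zupt', got {detrend!r}")
    a = trace.values
    t = np.arange(a.size) / trace.rate

    if detrend == "zupt":
        if stationary is None:
            stationary = detect_stationary(trace)
        stationary = np.asarray(stationary, dtype=bool)
        if stationary.shape != a.shape:
            raise ValueError("stationary mask length mismatch")
        if stationary.any():
            a = a - a[stationary].mean()
        else:  # no rest detected: fall back to endpoint anchoring
            a = a - a.mean()
            stationary = np.zeros(a.size, dtype=bool)
            stationary[0] = stationary[-1] = True
        v = cumulative_trapezoid(a, t, initial=0.0)
        idx = np.flatnonzero(stationary)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        # anchor the velocity random walk at the edge samples of every
        # stationary run; between runs the correction is the endpoint bridge
        anchor_t, anchor_v = [], []
        for run in runs:
            anchor_t.extend((t[run[0]], t[run[-1]]))
            anchor_v.extend((v[run[0]], v[run[-1]]))
        v = v - np.interp(t, anchor_t, anchor_v)
        v[stationary] = 0.0
    else:
        v = cumulative_trapezoid(a, t, initial=0.0)
        if detrend == "linear":
            v = signal.detrend(v, type="linear")

    p = cumulative_trapezoid(v, t, initial=0.0)
    if detrend == "linear":
        p = signal.detrend(p, type="linear")
    p = p - p[0]
    out = SignalTrace(
        values=p * 100.0,
        rate=trace.rate,
        start_time=trace.start_time,
        label="displacement",
        units="cm",
    )
    return DisplacementTrace(trace=out)


def net_displacement(d: DisplacementTrace) -> float:
    """Net anterior displacement in cm (last minus first sample)."""
    return d.net


def movement_direction(
    trace: SignalTrace, threshold: float, min_gap_s: float = 0.3
) -> list[MovementEvent]:
    """Detect movement bursts and their directions from signal phase.

    Samples with ``|a| > threshold`` are grouped into bursts (gaps shorter
    than ``min_gap_s`` merged, so one biphasic accelerate/decelerate pulse is
    a single event).  The sign of the first supra-threshold excursion sets
    the direction: rising edge first -> forward, falling edge first ->
    backward.  Returns an empty list if nothing crosses the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    a = trace.values
    above = np.flatnonzero(np.abs(a) > threshold)
    if above.size == 0:
        return []
    gap = max(1, int(round(min_gap_s * trace.rate)))
    bursts = np.split(above, np.flatnonzero(np.diff(above) > gap) + 1)
    events = []
    for burst in bursts:
        first = burst[0]
        direction = "forward" if a[first] > 0 else "backward"
        events.append(
            MovementEvent(
                onset_time=float(trace.start_time + first / trace.rate),
                direction=direction,
            )
        )
    return events


def log_linearity_check(real_disp, integrator_out) -> tuple[float, float]:
    """OLS fit of log(integrator output) against log(real displacement).

    Returns ``(slope, pearson_r)``.  A slope of 1 with r ~ 1 means the
    integrator output is proportional to true displacement; amplitude-like
    outputs that grow as a power of displacement appear as other slopes but
    still with high correlation on the log-log scale.
    """
    x = np.asarray(real_disp, dtype=float)
    y = np.asarray(integrator_out, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log-log fit requires strictly positive values")
    res = stats.linregress(np.log(x), np.log(y))
    return float(res.slope), float(res.rvalue)
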