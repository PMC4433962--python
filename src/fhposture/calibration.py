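"""Voltage <-> angle calibration for the flex sensor and accelerometer axes.

A posture sensor head combines a resistive flex sensor worn at the back of
the neck with a three-axis accelerometer worn at the ear.  Each channel is
characterised on the bench by a table of output voltage (mV) versus applied
bend/tilt angle (degrees).  This module loads such a table, fits per-channel
calibrations (an exact piecewise-linear interpolant through the nodes plus an
ordinary-least-squares affine summary, since the response is close to
linear), and converts between voltage and angle in either direction.

A reference table spanning -60..60 degrees in 10-degree steps for four
channels (``flex``, ``x``, ``y``, ``z``) ships with the package::

    from fhposture.calibration import bundled_table_path, load_calibration_table
    table = load_calibration_table(bundled_table_path())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationError",
    "CalibrationTable",
    "ChannelCalibration",
    "bundled_table_path",
    "load_calibration_table",
    "fit_channel_calibration",
    "voltage_to_angle",
    "angle_to_voltage",
]


class CalibrationError(ValueError):
    """Raised for malformed calibration tables or out-of-range conversions."""


@dataclass(frozen=True)
class CalibrationTable:
    """Voltage-versus-angle samples for a set of named sensor channels.

    Parameters
    ----------
    degrees
        Strictly increasing applied angles in degrees (>= 2 nodes).
    channels
        Mapping from channel name to the measured voltages (mV), one value
        per entry of ``degrees``.  Every column must be strictly increasing:
        all supported sensors respond monotonically over their working range.
    """

    degrees: np.ndarray
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        degrees = np.asarray(self.degrees, dtype=float)
        object.__setattr__(self, "degrees", degrees)
        if degrees.ndim != 1 or degrees.size < 2:
            raise CalibrationError("calibration table needs at least 2 degree nodes")
        if not np.all(np.diff(degrees) > 0):
            raise CalibrationError("degree nodes must be strictly increasing")
        channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        object.__setattr__(self, "channels", channels)
        if not channels:
            raise CalibrationError("calibration table has no voltage channels")
        for name, col in channels.items():
            if col.shape != degrees.shape:
                raise CalibrationError(
                    f"channel {name!r} has {col.size} values for {degrees.size} nodes"
                )
            if np.any(~np.isfinite(col)):
                raise CalibrationError(f"channel {name!r} contains non-finite values")
            if not np.all(np.diff(col) > 0):
                raise CalibrationError(
                    f"channel {name!r} voltages are not strictly increasing"
                )

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)


@dataclass(frozen=True)
class ChannelCalibration:
    """Fitted voltage<->angle maps for one channel.

    Holds the interpolation nodes, an exact piecewise-linear interpolant
    through them, and an OLS affine fit ``v ~ intercept + slope * degree``
    summarising the (nearly linear) response.
    """

    channel: str
    degrees: np.ndarray
    voltages: np.ndarray
    slope: float  # mV per degree, > 0
    intercept: float  # mV at 0 degrees (affine fit)
    residual_rms: float  # mV, RMS of affine-fit residuals at the nodes
    affine_tolerance: float = field(default=np.inf, repr=False)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(f"channel {self.channel!r}: fitted slope not positive")
        resid = self.intercept + self.slope * self.degrees - self.voltages
        if np.max(np.abs(resid)) > self.affine_tolerance:
            raise CalibrationError(
                f"channel {self.channel!r}: affine fit misses a node by more than "
                f"{self.affine_tolerance} mV (linearity check failed)"
            )

    @property
    def voltage_range(self) -> tuple[float, float]:
        return float(self.voltages[0]), float(self.voltages[-1])

    @property
    def degree_range(self) -> tuple[float, float]:
        return float(self.degrees[0]), float(self.degrees[-1])


def bundled_table_path() -> Path:
    """Path of the calibration table shipped with the package."""
    return Path(resources.files("fhposture") / "data" / "voltage_angle_table.csv")


def load_calibration_table(path: str | Path) -> CalibrationTable:
    """Read a calibration CSV with header ``degree,<ch1>,<ch2>,...``.

    One row per node; the first column is the applied angle in degrees, the
    remaining columns are per-channel voltages in mV.  Raises
    :class:`CalibrationError` on missing cells, non-monotone degrees or
    non-monotone voltage columns.
    """
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise CalibrationError("calibration CSV needs a degree column and >= 1 channel")
    if frame.columns[0] != "degree":
        raise CalibrationError(
            f"first column must be 'degree', got {frame.columns[0]!r}"
        )
    if frame.isna().any().any():
        raise CalibrationError("calibration CSV has missing cells")
    degrees = frame["degree"].to_numpy(dtype=float)
    channels = {
        str(name): frame[name].to_numpy(dtype=float) for name in frame.columns[1:]
    }
    return CalibrationTable(degrees=degrees, channels=channels)


def fit_channel_calibration(
    table: CalibrationTable, channel: str, affine_tolerance: float = np.inf
) -> ChannelCalibration:
    """Fit one channel's calibration from the table.

    The piecewise-linear interpolant reproduces every node exactly; the OLS
    affine fit provides a slope/intercept summary and its residual RMS.  Set
    ``affine_tolerance`` (mV) to enforce the linearity claim at every node.
    """
    if channel not in table.channels:
        raise CalibrationError(
            f"unknown channel {channel!r}; table has {table.channel_names}"
        )
    deg = table.degrees
    volt = table.channels[channel]
    # normal-equation OLS of voltage on degree
    slope, intercept = np.polyfit(deg, volt, 1)
    resid = volt - (intercept + slope * deg)
    return ChannelCalibration(
        channel=channel,
        degrees=deg.copy(),
        voltages=volt.copy(),
        slope=float(slope),
        intercept=float(intercept),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        affine_tolerance=affine_tolerance,
    )


def _check_range(x, lo: float, hi: float, what: str, extrapolate: bool) -> None:
    if extrapolate:
        return
    x = np.asarray(x, dtype=float)
    if np.any(x < lo) or np.any(x > hi):
        raise CalibrationError(
            f"{what} outside calibrated range [{lo}, {hi}] "
            "(pass extrapolate=True to allow affine extrapolation)"
        )


def voltage_to_angle(
    cal: ChannelCalibration,
    v,
    mode: str = "interpolant",
    extrapolate: bool = False,
):
    """Convert voltage (mV) to sensor angle (degrees).

    ``mode='interpolant'`` inverts the piecewise-linear node map (exact at the
    nodes, strictly increasing in between); ``mode='affine'`` inverts the OLS
    fit.  Out-of-range voltages raise unless ``extrapolate`` is set, in which
    case the affine fit extends the map.
    """
    v_arr = np.asarray(v, dtype=float)
    if mode == "interpolant":
        lo, hi = cal.voltage_range
        _check_range(v_arr, lo, hi, "voltage", extrapolate)
        out = np.interp(v_arr, cal.voltages, cal.degrees)
        if extrapolate:
            out = np.where(v_arr < lo, (v_arr - cal.intercept) / cal.slope, out)
            out = np.where(v_arr > hi, (v_arr - cal.intercept) / cal.slope, out)
    elif mode == "affine":
        out = (v_arr - cal.intercept) / cal.slope
    else:
        raise ValueError(f"mode must be 'interpolant' or 'affine', got {mode!r}")
    return float(out) if np.isscalar(v) or np.ndim(v) == 0 else out


def angle_to_voltage(
    cal: ChannelCalibration,
    a,
    mode: str = "interpolant",
    extrapolate: bool = False,
):
    """Convert sensor angle (degrees) to voltage (mV); inverse of
    :func:`voltage_to_angle` to machine precision within the node range."""
    a_arr = np.asarray(a, dtype=float)
    if mode == "interpolant":
        lo, hi = cal.degree_range
        _check_range(a_arr, lo, hi, "angle", extrapolate)
        out = np.interp(a_arr, cal.degrees, cal.voltages)
        if extrapolate:
            out = np.where(a_arr < lo, cal.intercept + cal.slope * a_arr, out)
            out = np.where(a_arr > hi, cal.intercept + cal.slope * a_arr, out)
    elif mode == "affine":
        out = cal.intercept + cal.slope * a_arr
    else:
        raise ValueError(f"mode must be 'interpolant' or 'affine', got {mode!r}")
    return float(out) if np.isscalar(a) or np.ndim(a) == 0 else out
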