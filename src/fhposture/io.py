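"""Sensor-log CSV reading and writing.

Schema: header ``t,vx,vy,vz,vflex``; ``t`` in seconds (uniform within 1%
jitter), voltages in mV.  The same schema is written by the simulator CLI,
so simulator output round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import SignalTrace

__all__ = ["SENSOR_COLUMNS", "read_sensor_log", "write_sensor_log",
           "write_ground_truth"]

SENSOR_COLUMNS = ("t", "vx", "vy", "vz", "vflex")
MAX_JITTER = 0.01  # relative deviation of any sample interval from the median


class SensorLogError(ValueError):
    """Raised for schema violations or non-uniform sampling."""


def read_sensor_log(path: str | Path) -> dict[str, SignalTrace]:
    """Read a sensor log, validating schema and sampling uniformity.

    Returns one :class:`SignalTrace` per voltage column, keyed by column
    name, all sharing the rate inferred from the median sample interval.
    """
    frame = pd.read_csv(path)
    missing = [c for c in SENSOR_COLUMNS if c not in frame.columns]
    if missing:
        raise SensorLogError(f"sensor log missing columns {missing}")
    if len(frame) < 2:
        raise SensorLogError("sensor log needs at least 2 rows")
    if frame[list(SENSOR_COLUMNS)].isna().any().any():
        raise SensorLogError("sensor log has missing values")
    t = frame["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SensorLogError("time stamps must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > MAX_JITTER * med:
        raise SensorLogError(
            f"non-uniform sampling: interval jitter exceeds {MAX_JITTER:.0%}"
        )
    rate = 1.0 / med
    return {
        col: SignalTrace(
            values=frame[col].to_numpy(dtype=float),
            rate=rate,
            start_time=float(t[0]),
            label=col,
            units="mV",
        )
        for col in SENSOR_COLUMNS[1:]
    }


def write_sensor_log(path: str | Path, traces: dict[str, SignalTrace]) -> None:
    """Write traces (keys ``vx,vy,vz,vflex``) to the sensor-log schema."""
    keys = SENSOR_COLUMNS[1:]
    missing = [k for k in keys if k not in traces]
    if missing:
        raise SensorLogError(f"traces missing channels {missing}")
    ref = traces[keys[0]]
    frame = pd.DataFrame({"t": ref.times})
    for k in keys:
        if traces[k].values.size != ref.values.size:
            raise SensorLogError("all channels must have equal length")
        frame[k] = traces[k].values
    frame.to_csv(path, index=False, float_format="%.6f")


def write_ground_truth(path: str | Path, truth) -> None:
    """Write a simulator :class:`~fhposture.simulator.GroundTruth` to CSV."""
    pd.DataFrame(
        {
            "t": truth.times,
            "displacement_cm": truth.displacement_cm,
            "velocity_mps": truth.velocity,
            "acceleration_mps2": truth.acceleration,
            "neck_angle_deg": truth.neck_angle,
            "head_angle_deg": truth.head_angle,
            "coronal_tilt_deg": truth.coronal_tilt,
        }
    ).to_csv(path, index=False, float_format="%.8f")
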