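"""Pipeline configuration: every tunable in one serialisable dataclass.

Defaults hold the published constants of the method: the 36-degree normal
cone, the 45-degree CV-angle threshold, the 1 / 2.5 / 5 cm severity bounds
and the 0.45 kg per 2.5 cm load increment.  Configs round-trip losslessly
through JSON (``save`` / ``load``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    # sampling / filtering
    sample_rate: float = 100.0  # Hz
    highpass_cutoff: float = 0.2  # Hz, gravity/bias DC rejection
    lowpass_cutoff: float = 10.0  # Hz, readout denoising
    filter_order: int = 4
    detrend: str = "zupt"  # displacement drift suppression mode
    # vector model
    cone_width: float = 36.0  # degrees, total
    cone_forward: float | None = None  # None -> symmetric split
    # assessment
    severity_bounds: tuple[float, float, float] = (1.0, 2.5, 5.0)  # cm
    cv_threshold: float = 45.0  # degrees, strict
    head_mass: float = 5.0  # kg
    load_increment: float = 0.45  # kg
    load_step: float = 2.5  # cm
    # sensor mapping
    channel_map: tuple[tuple[str, str], ...] = (
        ("flex", "flex"),
        ("x", "x"),
        ("y", "y"),
        ("z", "z"),
    )
    sensitivity: float | None = None  # mV/(m/s^2); None -> from calibration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not 0 < self.highpass_cutoff < self.sample_rate / 2:
            raise ValueError("highpass_cutoff must lie in (0, Nyquist)")
        if not 0 < self.lowpass_cutoff < self.sample_rate / 2:
            raise ValueError("lowpass_cutoff must lie in (0, Nyquist)")
        if self.detrend not in ("none", "linear", "zupt"):
            raise ValueError(f"bad detrend mode {self.detrend!r}")
        b = self.severity_bounds
        if not (len(b) == 3 and 0 < b[0] < b[1] < b[2]):
            raise ValueError("severity_bounds must be 3 increasing positive values")
        if not 0 < self.cv_threshold <= 90:
            raise ValueError("cv_threshold must lie in (0, 90]")
        if min(self.head_mass, self.load_increment, self.load_step) <= 0:
            raise ValueError("load-model parameters must be positive")
        object.__setattr__(self, "severity_bounds", tuple(float(x) for x in b))
        object.__setattr__(
            self, "channel_map", tuple((str(a), str(b_)) for a, b_ in self.channel_map)
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["severity_bounds"] = list(self.severity_bounds)
        out["channel_map"] = {k: v for k, v in self.channel_map}
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "severity_bounds" in data:
            data["severity_bounds"] = tuple(data["severity_bounds"])
        if "channel_map" in data and isinstance(data["channel_map"], dict):
            data["channel_map"] = tuple(data["channel_map"].items())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def channel(self, role: str) -> str:
        """Column name serving the given sensor role (flex, x, y, z)."""
        mapping = dict(self.channel_map)
        if role not in mapping:
            raise KeyError(f"no channel mapped for role {role!r}")
        return mapping[role]
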