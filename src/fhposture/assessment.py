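"""Clinical-style forward-head-posture assessment.

Combines the parallel diagnostic criteria into one report:

* severity class from anterior head displacement (calliper-style bands:
  under 1 cm none, 1-2.5 cm slight, 2.5-5 cm severe, 5 cm and beyond highly
  severe; lower bounds inclusive),
* the craniovertebral (CV) angle screen — FHP is flagged when the CV angle
  falls strictly below 45 degrees,
* the vector-model cone test (see :mod:`fhposture.vector_model`),
* the mechanical consequence: effective head load grows by 0.45 kg for every
  2.5 cm of forward displacement (read as a continuous 0.18 kg/cm here, with
  a discrete staircase mode available), and the neck moment is that load
  times gravity times the anterior lever arm.

The criteria are reported side by side; no fusion between displacement
severity and the vector deviation is invented.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .vector_model import (
    AngleState,
    NormalCone,
    PostureVector,
    STANDARD_GRAVITY,
    classify_vector,
    compose_vector,
)

__all__ = [
    "Severity",
    "LoadModel",
    "FHPAssessment",
    "DEFAULT_SEVERITY_BOUNDS",
    "classify_displacement",
    "effective_head_load",
    "neck_moment",
    "cv_angle_flag",
    "cv_angle_from_neck",
    "assess",
]

#: Lower bounds (cm) of the slight / severe / highly-severe bands.
DEFAULT_SEVERITY_BOUNDS: tuple[float, float, float] = (1.0, 2.5, 5.0)

DEFAULT_CV_THRESHOLD = 45.0  # degrees, strict inequality


class Severity(str, enum.Enum):
    NONE = "none"
    SLIGHT = "slight"
    SEVERE = "severe"
    HIGHLY_SEVERE = "highly_severe"


@dataclass(frozen=True)
class LoadModel:
    """Head-load parameters: base mass plus a forward-displacement surcharge.

    Defaults: 5.0 kg base head mass (midpoint of the typical 4.5-5.5 kg
    range), +0.45 kg per 2.5 cm of forward displacement.
    """

    head_mass: float = 5.0  # kg
    increment: float = 0.45  # kg per step
    step: float = 2.5  # cm
    gravity: float = STANDARD_GRAVITY  # m/s^2

    def __post_init__(self) -> None:
        if min(self.head_mass, self.increment, self.step, self.gravity) <= 0:
            raise ValueError("all load-model parameters must be positive")


@dataclass(frozen=True)
class FHPAssessment:
    """Aggregated posture assessment; see module docstring for semantics."""

    severity: Severity
    net_displacement_cm: float
    cv_angle_deg: float
    cv_flag: bool
    deviation_deg: float
    sagittal_deviation_deg: float
    vector_inside_cone: bool
    effective_load_kg: float
    neck_moment_nm: float
    posture_vector: PostureVector = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "severity": self.severity.value,
            "net_displacement_cm": self.net_displacement_cm,
            "cv_angle_deg": self.cv_angle_deg,
            "cv_flag": self.cv_flag,
            "deviation_deg": self.deviation_deg,
            "sagittal_deviation_deg": self.sagittal_deviation_deg,
            "inside_cone": self.vector_inside_cone,
            "effective_load_kg": self.effective_load_kg,
            "neck_moment_nm": self.neck_moment_nm,
            "posture_vector": [float(c) for c in self.posture_vector.components],
        }


def classify_displacement(
    d: float, bounds: tuple[float, float, float] = DEFAULT_SEVERITY_BOUNDS
) -> Severity:
    """Severity class of an anterior displacement ``d`` (cm, >= 0).

    Bands are lower-inclusive: ``[0, b0) -> none, [b0, b1) -> slight,
    [b1, b2) -> severe, [b2, inf) -> highly severe``.
    """
    if d < 0:
        raise ValueError("displacement must be non-negative")
    b0, b1, b2 = bounds
    if not 0 < b0 < b1 < b2:
        raise ValueError("severity bounds must be positive and increasing")
    if d < b0:
        return Severity.NONE
    if d < b1:
        return Severity.SLIGHT
    if d < b2:
        return Severity.SEVERE
    return Severity.HIGHLY_SEVERE


def effective_head_load(
    model: LoadModel, d: float, mode: str = "continuous"
) -> float:
    """Effective head load (kg) at forward displacement ``d`` cm.

    ``continuous`` (default): base + increment * d / step.
    ``staircase``: base + increment per completed step (discrete reading of
    the same rule).
    """
    if d < 0:
        raise ValueError("displacement must be non-negative")
    if mode == "continuous":
        return model.head_mass + model.increment * d / model.step
    if mode == "staircase":
        return model.head_mass + model.increment * np.floor(d / model.step)
    raise ValueError(f"mode must be 'continuous' or 'staircase', got {mode!r}")


def neck_moment(model: LoadModel, d: float, mode: str = "continuous") -> float:
    """Moment about the cervical pivot in N*m: load * g * lever arm (d in m).

    Zero at zero displacement, strictly increasing in ``d``.
    """
    return effective_head_load(model, d, mode) * model.gravity * (d / 100.0)


def cv_angle_flag(cv: float, threshold: float = DEFAULT_CV_THRESHOLD) -> bool:
    """True if the CV angle indicates FHP (strictly below the threshold)."""
    if not 0.0 <= cv <= 90.0:
        raise ValueError(f"CV angle {cv} outside [0, 90] degrees")
    return cv < threshold


def cv_angle_from_neck(
    neck_angle: float, scale: float = 1.0, reference: float = 90.0
) -> float:
    """CV-angle proxy from the neck angle: ``reference - scale * neck_angle``.

    A validated conversion between the neck angle and the clinical CV angle
    does not exist yet; the default identity-on-(90 - neck) mapping treats an
    upright neck as a 90-degree CV angle and clips to the valid [0, 90] range.
    The affine parameters are exposed so a future calibration can be dropped
    in.
    """
    return float(np.clip(reference - scale * neck_angle, 0.0, 90.0))


def assess(
    displacement: float,
    angles: AngleState,
    cone: NormalCone | None = None,
    model: LoadModel | None = None,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    severity_bounds: tuple[float, float, float] = DEFAULT_SEVERITY_BOUNDS,
    cv_angle: float | None = None,
) -> FHPAssessment:
    """Produce the full FHP assessment for one posture observation.

    ``displacement`` is the net anterior head displacement in cm; ``angles``
    the measured neck/head angle state.  The CV angle defaults to the
    :func:`cv_angle_from_neck` proxy unless measured directly.  Pure
    function: identical inputs give identical outputs.
    """
    cone = cone if cone is not None else NormalCone()
    model = model if model is not None else LoadModel()
    vector = compose_vector(angles)
    if cv_angle is None:
        cv_angle = cv_angle_from_neck(angles.neck_angle)
    return FHPAssessment(
        severity=classify_displacement(displacement, severity_bounds),
        net_displacement_cm=float(displacement),
        cv_angle_deg=float(cv_angle),
        cv_flag=cv_angle_flag(cv_angle, cv_threshold),
        deviation_deg=vector.deviation,
        sagittal_deviation_deg=vector.sagittal_deviation,
        vector_inside_cone=classify_vector(vector, cone),
        effective_load_kg=effective_head_load(model, displacement),
        neck_moment_nm=neck_moment(model, displacement),
        posture_vector=vector,
    )
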