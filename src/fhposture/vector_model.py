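"""Two-angle vector-sum posture model.

Posture is summarised by two sagittal angles anchored at the first cervical
vertebra (C1): the neck angle measured by the flex sensor and the head angle
derived from the accelerometer's gravity components (which also yield an
optional coronal tilt).  Each angle defines a unit segment vector tilted
from vertical; their (weighted) sum, renormalised, is the posture vector.
Posture is judged correct while the vector's signed sagittal deviation from
vertical stays inside a normal-range cone — 36 degrees total width by
default, split symmetrically forward/backward.

Axis convention: ``(anterior, lateral, vertical)``; forward (anterior)
deviation is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AngleState",
    "PostureVector",
    "NormalCone",
    "head_tilt_from_acceleration",
    "segment_vector",
    "compose_vector",
    "classify_vector",
]

STANDARD_GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class AngleState:
    """Neck angle (flex sensor) and head angle (accelerometer), degrees.

    Sagittal angles; 0 = upright, positive = forward.  ``coronal_tilt`` is
    the sideways head tilt, applied to the head segment only.
    """

    neck_angle: float
    head_angle: float
    coronal_tilt: float = 0.0

    def __post_init__(self) -> None:
        for name in ("neck_angle", "head_angle", "coronal_tilt"):
            val = getattr(self, name)
            if not -90.0 <= val <= 90.0:
                raise ValueError(f"{name}={val} outside [-90, 90] degrees")


@dataclass(frozen=True)
class PostureVector:
    """Unit posture vector in (anterior, lateral, vertical) axes."""

    components: np.ndarray
    reference: str = "C1"

    def __post_init__(self) -> None:
        comp = np.asarray(self.components, dtype=float)
        object.__setattr__(self, "components", comp)
        if comp.shape != (3,):
            raise ValueError("posture vector needs 3 components")
        if abs(np.linalg.norm(comp) - 1.0) > 1e-9:
            raise ValueError("posture vector must be unit length")

    @property
    def deviation(self) -> float:
        """Total angular deviation from vertical, degrees (arccos of the
        vertical component)."""
        return float(np.degrees(np.arccos(np.clip(self.components[2], -1.0, 1.0))))

    @property
    def sagittal_deviation(self) -> float:
        """Signed sagittal deviation, degrees; forward positive."""
        return float(np.degrees(np.arctan2(self.components[0], self.components[2])))


@dataclass(frozen=True)
class NormalCone:
    """Angular range around vertical within which posture is correct.

    ``forward + backward = width``; the default 36-degree total width is
    split symmetrically (18 forward / 18 backward) unless a split is given.
    """

    width: float = 36.0
    forward: float | None = None
    backward: float | None = None

    def __post_init__(self) -> None:
        fwd = self.width / 2.0 if self.forward is None else float(self.forward)
        bwd = self.width - fwd if self.backward is None else float(self.backward)
        object.__setattr__(self, "forward", fwd)
        object.__setattr__(self, "backward", bwd)
        if fwd < 0 or bwd < 0:
            raise ValueError("cone half-widths must be non-negative")
        if abs(fwd + bwd - self.width) > 1e-9:
            raise ValueError("forward + backward must equal the total width")


def head_tilt_from_acceleration(
    gx: float,
    gy: float,
    gz: float,
    magnitude_tolerance: float = 0.2,
    gravity: float = STANDARD_GRAVITY,
) -> tuple[float, float]:
    """Head tilt angles (sagittal, coronal) in degrees from static gravity
    components measured on the (anterior, lateral, vertical) axes.

    Valid only quasi-statically: the vector magnitude must be within
    ``magnitude_tolerance`` (relative) of standard gravity, otherwise the
    device is accelerating and a ``ValueError`` is raised.

    Standard pitch/roll formulas: sagittal ``atan2(gx, gz)``, coronal
    ``atan2(gy, sqrt(gx^2 + gz^2))`` — the exact inverse of
    :func:`segment_vector`, reducing to lateral-vs-vertical arctangent when
    the sagittal tilt is zero.
    """
    mag = float(np.sqrt(gx * gx + gy * gy + gz * gz))
    if abs(mag - gravity) > magnitude_tolerance * gravity:
        raise ValueError(
            f"|g|={mag:.3f} m/s^2 deviates more than {magnitude_tolerance:.0%} from "
            f"{gravity}; device appears to be in motion"
        )
    sagittal = float(np.degrees(np.arctan2(gx, gz)))
    coronal = float(np.degrees(np.arctan2(gy, np.hypot(gx, gz))))
    return sagittal, coronal


def segment_vector(sagittal_deg: float, coronal_deg: float = 0.0) -> np.ndarray:
    """Unit vector of a body segment tilted from vertical.

    Sagittal tilt rotates toward anterior, coronal tilt toward lateral:
    ``(sin s cos c, sin c, cos s cos c)`` — unit norm for any angles.
    """
    s = np.radians(sagittal_deg)
    c = np.radians(coronal_deg)
    return np.array(
        [np.sin(s) * np.cos(c), np.sin(c), np.cos(s) * np.cos(c)], dtype=float
    )


def compose_vector(
    state: AngleState, weights: tuple[float, float] = (1.0, 1.0)
) -> PostureVector:
    """Sum the neck and head segment vectors and renormalise.

    The neck segment is tilted by the neck angle in the sagittal plane; the
    head segment by the head angle plus any coronal tilt.  ``weights`` scales
    (neck, head) before summation — equal unit weights by default.
    """
    w_neck, w_head = weights
    total = w_neck * segment_vector(state.neck_angle) + w_head * segment_vector(
        state.head_angle, state.coronal_tilt
    )
    norm = np.linalg.norm(total)
    if norm < 1e-12:
        raise ValueError("segment vectors cancel; posture vector undefined")
    return PostureVector(components=total / norm)


def classify_vector(vector: PostureVector, cone: NormalCone) -> bool:
    """True if the posture vector lies inside the normal cone.

    Inside iff the signed sagittal deviation is within
    ``[-backward, +forward]``; boundaries count as inside.
    """
    dev = vector.sagittal_deviation
    return -cone.backward <= dev <= cone.forward
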