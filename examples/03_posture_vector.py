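"""Combine neck and head angles into the posture vector and test the cone.

The neck angle comes from the flex sensor, the head angle from the
accelerometer's gravity components.  Each angle tilts a unit segment vector
from vertical; their renormalised sum is the posture vector, and posture is
correct while its sagittal deviation stays inside the 36-degree normal cone
(18 forward / 18 backward by default).
"""

import numpy as np

from fhposture import (
    AngleState,
    NormalCone,
    classify_vector,
    compose_vector,
    head_tilt_from_acceleration,
)

g = 9.81
# gravity components a resting accelerometer would read at a 25-degree tilt
gx, gy, gz = g * np.sin(np.radians(25.0)), 0.0, g * np.cos(np.radians(25.0))
head_sag, head_cor = head_tilt_from_acceleration(gx, gy, gz)
print(f"head tilt from gravity ({gx:.2f}, {gy:.2f}, {gz:.2f}) m/s^2 -> "
      f"sagittal {head_sag:.1f} deg, coronal {head_cor:.1f} deg")

cone = NormalCone()
for neck, head in [(0.0, 0.0), (10.0, 15.0), (25.0, 30.0)]:
    v = compose_vector(AngleState(neck_angle=neck, head_angle=head))
    inside = classify_vector(v, cone)
    print(f"neck {neck:5.1f} deg, head {head:5.1f} deg -> deviation "
          f"{v.sagittal_deviation:5.1f} deg, {'inside' if inside else 'OUTSIDE'} "
          f"the {cone.width:.0f}-degree cone")

print("(a vector outside the cone flags forward head posture regardless of "
      "how the two angles individually look)")
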