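"""Metric, gravity-aligned calibration from the in-scene references.

The blue rectangle of known physical length gives the scale
(cm per pixel); the red plumb string gives the true vertical.  A
:class:`Calibration` converts image pixels (origin top-left, x right,
y down) into a world frame in cm with y up and the plumb direction
exactly vertical.

Conventions, stated once and enforced everywhere: pixel centers sit at
integer coordinates; ``rotation_deg`` is the angle that rotates image
axes so the plumb direction becomes the world vertical, positive for a
plumb leaning toward +x (image clockwise from vertical); it must lie in
(−45°, 45°].  No parallax or perspective correction is applied — a
single global scale per image.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .detection import PlumbLineObservation, RectangleObservation
from .errors import CalibrationError


@dataclass(frozen=True)
class Calibration:
    cm_per_px: float
    rotation_deg: float
    origin_px: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.cm_per_px <= 0:
            raise CalibrationError("cm_per_px must be positive")
        if not (-45.0 < self.rotation_deg <= 45.0):
            raise CalibrationError("rotation must lie in (-45, 45] degrees")

    def to_json(self) -> str:
        return json.dumps({"cm_per_px": self.cm_per_px,
                           "rotation_deg": self.rotation_deg,
                           "origin_px": list(self.origin_px)})

    @classmethod
    def from_json(cls, s: str) -> "Calibration":
        d = json.loads(s)
        return cls(d["cm_per_px"], d["rotation_deg"], tuple(d["origin_px"]))


def compute_scale(rect: RectangleObservation, known_length_cm: float) -> float:
    """Scale in cm per pixel from the rectangle's long-axis pixel length."""
    if known_length_cm <= 0:
        raise ValueError("known length must be positive")
    if rect.length_px <= 0:
        raise ValueError("rectangle pixel length must be positive")
    return known_length_cm / rect.length_px


def build_frame(rect: RectangleObservation | None,
                plumb: PlumbLineObservation | None,
                known_length_cm: float = 20.0,
                origin_px: tuple = (0.0, 0.0)) -> Calibration:
    """Combine both reference observations into a Calibration."""
    missing = []
    if rect is None:
        missing.append("scale rectangle not found")
    if plumb is None:
        missing.append("plumb line not found")
    if missing:
        raise CalibrationError("calibration incomplete: " + "; ".join(missing))
    dx, dy = plumb.direction
    if dy < 0:
        dx, dy = -dx, -dy
    rotation = math.degrees(math.atan2(dx, dy))
    return Calibration(cm_per_px=compute_scale(rect, known_length_cm),
                       rotation_deg=rotation, origin_px=tuple(origin_px))


def to_world(point_px, cal: Calibration) -> np.ndarray:
    """Pixel → world cm: rotate about the origin by −rotation (so the
    plumb becomes vertical), flip y to point up, scale to cm."""
    p = np.asarray(point_px, dtype=float) - np.asarray(cal.origin_px, dtype=float)
    th = math.radians(cal.rotation_deg)
    c, s = math.cos(th), math.sin(th)
    # rotate image coordinates by -rotation
    x = c * p[0] - s * p[1]
    y = s * p[0] + c * p[1]
    return np.array([x * cal.cm_per_px, -y * cal.cm_per_px])
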