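"""Body-frame posture templates and their deformation model.

A :class:`PostureTemplate` places every marker site of one view in a
normalized, isotropic body frame: ``x`` runs 0→1 from the subject's left
to the subject's right, ``y`` runs 0→1 from the feet to the head.  Both
axes share the same physical unit (one subject height), so rotations in
this frame are true rotations.

Posture deviations are modeled as small affine displacements of the
landmark groups they anatomically involve:

* ``pelvic_obliquity_deg`` rotates the ASIS pair (anterior) and the PSIS
  pair (posterior) about the pelvis midpoint — positive tilts the
  subject's right side up.
* ``shoulder_drop_deg`` rotates the acromion pair about its midpoint.
* ``kyphosis_gain`` displaces the thoracic kyphosis apex posteriorly in
  the lateral views (sagittal bulge), in units of 0.05 body heights.
* ``lordosis_gain`` displaces the lumbar lordosis apex anteriorly in the
  lateral views, same units.
* ``scoliosis_offset`` shifts the kyphosis apex laterally in the
  posterior view (frontal-plane spinal deviation), in body-height units.

The model deliberately moves exactly the landmarks whose features a given
severity class should move, and nothing else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .sites import (
    ANTERIOR, POSTERIOR, LATERAL_LEFT, LATERAL_RIGHT, VIEWS,
    VIEW_MIRRORED, VIEW_SITES,
)

PERTURBATION_NAMES = (
    "pelvic_obliquity_deg",
    "shoulder_drop_deg",
    "kyphosis_gain",
    "lordosis_gain",
    "scoliosis_offset",
)


@dataclass(frozen=True)
class Perturbations:
    pelvic_obliquity_deg: float = 0.0
    shoulder_drop_deg: float = 0.0
    kyphosis_gain: float = 0.0
    lordosis_gain: float = 0.0
    scoliosis_offset: float = 0.0

    @classmethod
    def from_dict(cls, d: dict) -> "Perturbations":
        unknown = set(d) - set(PERTURBATION_NAMES)
        if unknown:
            raise ValueError(f"unknown perturbation(s): {sorted(unknown)}")
        return cls(**d)

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in PERTURBATION_NAMES}


@dataclass(frozen=True)
class PostureTemplate:
    """Marker-site layout of one view in the normalized body frame."""

    view: str
    landmarks: dict  # site key -> (x, y) in [0,1]^2, subject frame
    perturbations: Perturbations = field(default_factory=Perturbations)

    def __post_init__(self):
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        missing = set(VIEW_SITES[self.view]) - set(self.landmarks)
        if missing:
            raise ValueError(
                f"template for {self.view} lacks required sites: {sorted(missing)}")

    def perturbed(self, pert: Perturbations | dict | None = None) -> "PostureTemplate":
        """Apply the deformation model; returns a new template."""
        if pert is None:
            pert = self.perturbations
        elif isinstance(pert, dict):
            pert = Perturbations.from_dict(pert)
        lm = {k: np.asarray(v, dtype=float) for k, v in self.landmarks.items()}

        def rotate_pair(a, b, deg):
            if a in lm and b in lm:
                mid = (lm[a] + lm[b]) / 2.0
                th = math.radians(deg)
                rot = np.array([[math.cos(th), -math.sin(th)],
                                [math.sin(th), math.cos(th)]])
                lm[a] = mid + rot @ (lm[a] - mid)
                lm[b] = mid + rot @ (lm[b] - mid)

        if self.view == ANTERIOR:
            rotate_pair("ASIS_L", "ASIS_R", pert.pelvic_obliquity_deg)
            rotate_pair("acromion_L", "acromion_R", pert.shoulder_drop_deg)
        elif self.view == POSTERIOR:
            rotate_pair("PSIS_L", "PSIS_R", pert.pelvic_obliquity_deg)
            rotate_pair("acromion_L", "acromion_R", pert.shoulder_drop_deg)
            if "kyphosis_apex" in lm:
                lm["kyphosis_apex"] = lm["kyphosis_apex"] + \
                    np.array([pert.scoliosis_offset, 0.0])
        else:
            # sagittal direction: +x is posterior in the left lateral
            # template below, mirrored for the right lateral
            post = 1.0 if self.view == LATERAL_LEFT else -1.0
            if "kyphosis_apex" in lm:
                lm["kyphosis_apex"] = lm["kyphosis_apex"] + \
                    np.array([post * 0.05 * pert.kyphosis_gain, 0.0])
            if "lordosis_apex" in lm:
                lm["lordosis_apex"] = lm["lordosis_apex"] + \
                    np.array([-post * 0.05 * pert.lordosis_gain, 0.0])
        return replace(self,
                       landmarks={k: (float(v[0]), float(v[1])) for k, v in lm.items()},
                       perturbations=pert if isinstance(pert, Perturbations) else Perturbations())

    def image_frame_landmarks(self) -> dict:
        """Landmarks in a normalized *image* frame: x left→right on the
        photo (mirrored for the anterior view), y top→bottom."""
        mirror = VIEW_MIRRORED[self.view]
        out = {}
        for k, (x, y) in self.landmarks.items():
            xi = 1.0 - x if mirror else x
            out[k] = (xi, 1.0 - y)
        return out

    def world_landmarks_cm(self, subject_height_cm: float) -> dict:
        """Landmarks in subject-world cm: x toward the subject's right,
        y up, origin at the feet midline."""
        h = float(subject_height_cm)
        return {k: np.array([(x - 0.5) * h, y * h])
                for k, (x, y) in self.landmarks.items()}


# ---------------------------------------------------------------------------
# Neutral (zero-perturbation) default templates.  Anterior/posterior are
# bilaterally symmetric about x = 0.5; coordinates are plausible adult
# proportions (e.g. acromion at 0.81 heights, trochanter at 0.50).

_ANTERIOR_LM = {
    "jugular_notch": (0.50, 0.800),
    "xiphoid": (0.50, 0.710),
    "acromion_L": (0.360, 0.810), "acromion_R": (0.640, 0.810),
    "ASIS_L": (0.420, 0.520), "ASIS_R": (0.580, 0.520),
    "trochanter_L": (0.365, 0.500), "trochanter_R": (0.635, 0.500),
    "patella_L": (0.430, 0.280), "patella_R": (0.570, 0.280),
    "tibial_tuberosity_L": (0.432, 0.235), "tibial_tuberosity_R": (0.568, 0.235),
    "lateral_malleolus_L": (0.405, 0.040), "lateral_malleolus_R": (0.595, 0.040),
}

_POSTERIOR_LM = {
    "C7": (0.50, 0.840),
    "kyphosis_apex": (0.50, 0.700),
    "lordosis_apex": (0.50, 0.560),
    "acromion_L": (0.360, 0.810), "acromion_R": (0.640, 0.810),
    "PSIS_L": (0.455, 0.530), "PSIS_R": (0.545, 0.530),
    "trochanter_L": (0.365, 0.500), "trochanter_R": (0.635, 0.500),
    "popliteal_fossa_L": (0.425, 0.270), "popliteal_fossa_R": (0.575, 0.270),
    "posterior_intermalleolar_point_L": (0.415, 0.050),
    "posterior_intermalleolar_point_R": (0.585, 0.050),
    "calcaneus_L": (0.420, 0.015), "calcaneus_R": (0.580, 0.015),
}

# Left lateral: +x is posterior (the subject faces -x).
_LATERAL_LEFT_LM = {
    "C7": (0.520, 0.840),
    "kyphosis_apex": (0.585, 0.700),
    "lordosis_apex": (0.505, 0.560),
    "ASIS_L": (0.415, 0.520),
    "PSIS_L": (0.585, 0.530),
    "trochanter_L": (0.520, 0.500),
    "femur_lateral_condyle_L": (0.500, 0.270),
    "lateral_malleolus_L": (0.525, 0.040),
    "calcaneus_L": (0.590, 0.015),
    "fifth_metatarsal_L": (0.380, 0.012),
}


def _mirror_lm(lm: dict, l_to_r: bool = True) -> dict:
    out = {}
    for k, (x, y) in lm.items():
        nk = k[:-2] + "_R" if (l_to_r and k.endswith("_L")) else k
        out[nk] = (1.0 - x, y)
    return out


def default_template(view: str) -> PostureTemplate:
    """Neutral posture template for a view."""
    if view == ANTERIOR:
        return PostureTemplate(ANTERIOR, dict(_ANTERIOR_LM))
    if view == POSTERIOR:
        return PostureTemplate(POSTERIOR, dict(_POSTERIOR_LM))
    if view == LATERAL_LEFT:
        return PostureTemplate(LATERAL_LEFT, dict(_LATERAL_LEFT_LM))
    if view == LATERAL_RIGHT:
        return PostureTemplate(LATERAL_RIGHT, _mirror_lm(_LATERAL_LEFT_LM))
    raise ValueError(f"unknown view {view!r}")


def default_templates() -> dict:
    return {v: default_template(v) for v in VIEWS}
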