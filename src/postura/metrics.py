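"""The 38 anatomical features: angle and distance primitives plus the
feature table that maps each named parameter to its landmarks.

All primitives operate on calibrated world coordinates (cm, y up,
+x toward the subject's anatomical right).  Four primitive kinds cover
every feature:

* :func:`angle_to_horizontal` — signed alignment angle of a left→right
  landmark pair against the plumb-derived horizontal; positive when the
  subject's right end is higher.
* :func:`angle_at_vertex` — unsigned three-point angle in [0°, 180°]
  (a collinear spine reads 180°, not 0°).
* :func:`angle_between_lines` — angle between two undirected lines,
  acute convention [0°, 90°] by default.
* :func:`distance_cm` — Euclidean distance.

Features whose landmarks are missing are emitted as NaN, never imputed.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .sites import (
    ANTERIOR, POSTERIOR, LATERAL_LEFT, LATERAL_RIGHT,
    DISTANCE_FEATURES, FEATURE_NAMES,
)

logger = logging.getLogger(__name__)

_EPS = 1e-12


def _as_pt(p):
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ValueError("points must be 2-vectors")
    return a


def angle_to_horizontal(p_left, p_right) -> float:
    """Signed angle in (−90°, 90°] of the segment left→right against the
    world horizontal; positive when the right end is higher."""
    a, b = _as_pt(p_left), _as_pt(p_right)
    d = b - a
    if np.hypot(*d) < _EPS:
        raise ValueError("coincident points define no line")
    ang = math.degrees(math.atan2(d[1], d[0]))
    # fold onto (-90, 90]
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    return ang


def angle_at_vertex(a, b, c) -> float:
    """Unsigned angle at vertex ``b`` in [0°, 180°]."""
    a, b, c = _as_pt(a), _as_pt(b), _as_pt(c)
    u, v = a - b, c - b
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu < _EPS or nv < _EPS:
        raise ValueError("degenerate vertex: coincident points")
    cosang = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def angle_between_lines(p1, p2, q1, q2, acute: bool = True) -> float:
    """Angle between undirected lines p1p2 and q1q2.

    Acute convention returns [0°, 90°] (so left/right instances of a
    bilateral parameter are comparable); ``acute=False`` returns the
    medial angle in [0°, 180°] between the directed segments.
    """
    p1, p2, q1, q2 = map(_as_pt, (p1, p2, q1, q2))
    u, v = p2 - p1, q2 - q1
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu < _EPS or nv < _EPS:
        raise ValueError("degenerate line: coincident points")
    cosang = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    ang = math.degrees(math.acos(cosang))
    if acute and ang > 90.0:
        ang = 180.0 - ang
    return ang


def distance_cm(p1, p2) -> float:
    """Euclidean distance in cm."""
    a, b = _as_pt(p1), _as_pt(p2)
    return float(np.hypot(*(b - a)))


# ---------------------------------------------------------------------------
# feature table: name -> (kind, view, point keys)
#
# kinds: "horiz"  (left point, right point)
#        "vertex" (a, vertex, c)
#        "lines"  (p1, p2, q1, q2)
#        "dist"   (p1, p2)
# point keys are site keys; "mid:A+B" denotes the midpoint of two sites.

FEATURE_DEFS = {
    # anterior
    "AHA_A": ("horiz", ANTERIOR, ("acromion_L", "acromion_R")),
    "ASA": ("lines", ANTERIOR,
            ("jugular_notch", "xiphoid", "acromion_L", "acromion_R")),
    "ASISHA": ("horiz", ANTERIOR, ("ASIS_L", "ASIS_R")),
    "ASISLA_L": ("lines", ANTERIOR,
                 ("trochanter_L", "patella_L", "ASIS_L", "ASIS_R")),
    "ASISLA_R": ("lines", ANTERIOR,
                 ("trochanter_R", "patella_R", "ASIS_L", "ASIS_R")),
    "AKLA_L": ("lines", ANTERIOR,
               ("trochanter_L", "patella_L",
                "tibial_tuberosity_L", "lateral_malleolus_L")),
    "AKLA_R": ("lines", ANTERIOR,
               ("trochanter_R", "patella_R",
                "tibial_tuberosity_R", "lateral_malleolus_R")),
    "AJND_L": ("dist", ANTERIOR, ("jugular_notch", "acromion_L")),
    "AJND_R": ("dist", ANTERIOR, ("jugular_notch", "acromion_R")),
    "AAD_L": ("dist", ANTERIOR, ("acromion_L", "ASIS_L")),
    "AAD_R": ("dist", ANTERIOR, ("acromion_R", "ASIS_R")),
    "ALLL_L": ("dist", ANTERIOR, ("trochanter_L", "lateral_malleolus_L")),
    "ALLL_R": ("dist", ANTERIOR, ("trochanter_R", "lateral_malleolus_R")),
    # posterior
    "AHA_P": ("horiz", POSTERIOR, ("acromion_L", "acromion_R")),
    "AVA": ("lines", POSTERIOR,
            ("C7", "kyphosis_apex", "acromion_L", "acromion_R")),
    "TKA": ("vertex", POSTERIOR, ("C7", "kyphosis_apex", "lordosis_apex")),
    "LLA": ("vertex", POSTERIOR,
            ("kyphosis_apex", "lordosis_apex", "mid:PSIS_L+PSIS_R")),
    "PSISHA": ("horiz", POSTERIOR, ("PSIS_L", "PSIS_R")),
    "PSISLA_L": ("lines", POSTERIOR,
                 ("trochanter_L", "popliteal_fossa_L", "PSIS_L", "PSIS_R")),
    "PSISLA_R": ("lines", POSTERIOR,
                 ("trochanter_R", "popliteal_fossa_R", "PSIS_L", "PSIS_R")),
    # vertex at the popliteal fossa between the thigh line and the
    # shank line down to the intermalleolar point
    "PKLA_L": ("vertex", POSTERIOR,
               ("trochanter_L", "popliteal_fossa_L",
                "posterior_intermalleolar_point_L")),
    "PKLA_R": ("vertex", POSTERIOR,
               ("trochanter_R", "popliteal_fossa_R",
                "posterior_intermalleolar_point_R")),
    "ALA_L": ("vertex", POSTERIOR,
              ("popliteal_fossa_L", "posterior_intermalleolar_point_L",
               "calcaneus_L")),
    "ALA_R": ("vertex", POSTERIOR,
              ("popliteal_fossa_R", "posterior_intermalleolar_point_R",
               "calcaneus_R")),
    "APD_L": ("dist", POSTERIOR, ("acromion_L", "PSIS_L")),
    "APD_R": ("dist", POSTERIOR, ("acromion_R", "PSIS_R")),
    "PLLL_L": ("dist", POSTERIOR, ("trochanter_L", "calcaneus_L")),
    "PLLL_R": ("dist", POSTERIOR, ("trochanter_R", "calcaneus_R")),
    # lateral
    "TKC_L": ("vertex", LATERAL_LEFT, ("C7", "kyphosis_apex", "lordosis_apex")),
    "TKC_R": ("vertex", LATERAL_RIGHT, ("C7", "kyphosis_apex", "lordosis_apex")),
    "LLC_L": ("vertex", LATERAL_LEFT, ("kyphosis_apex", "lordosis_apex", "PSIS_L")),
    "LLC_R": ("vertex", LATERAL_RIGHT, ("kyphosis_apex", "lordosis_apex", "PSIS_R")),
    "PLA_L": ("lines", LATERAL_LEFT,
              ("ASIS_L", "PSIS_L", "trochanter_L", "femur_lateral_condyle_L")),
    "PLA_R": ("lines", LATERAL_RIGHT,
              ("ASIS_R", "PSIS_R", "trochanter_R", "femur_lateral_condyle_R")),
    "KA_L": ("vertex", LATERAL_LEFT,
             ("trochanter_L", "femur_lateral_condyle_L", "lateral_malleolus_L")),
    "KA_R": ("vertex", LATERAL_RIGHT,
             ("trochanter_R", "femur_lateral_condyle_R", "lateral_malleolus_R")),
    "LFA_L": ("lines", LATERAL_LEFT,
              ("trochanter_L", "femur_lateral_condyle_L",
               "calcaneus_L", "fifth_metatarsal_L")),
    "LFA_R": ("lines", LATERAL_RIGHT,
              ("trochanter_R", "femur_lateral_condyle_R",
               "calcaneus_R", "fifth_metatarsal_R")),
}

assert tuple(FEATURE_DEFS) == FEATURE_NAMES  # single source of truth


def _resolve(key: str, pts: dict):
    if key.startswith("mid:"):
        a, b = key[4:].split("+")
        if a not in pts or b not in pts:
            return None
        return (np.asarray(pts[a], float) + np.asarray(pts[b], float)) / 2.0
    if key not in pts:
        return None
    return np.asarray(pts[key], float)


def compute_features(world_views: dict, acute_line_angles: bool = True) -> dict:
    """Compute all 38 features from per-view world-coordinate landmarks.

    ``world_views`` maps view name → {site → (x, y) cm in the subject
    world frame} (see :meth:`LandmarkSet.world_points`).  Features whose
    view or landmarks are absent come back NaN.
    """
    absent_views = {v for v, _, _ in
                    ((d[1], None, None) for d in FEATURE_DEFS.values())
                    } - set(world_views)
    for v in sorted(absent_views):
        logger.warning("view %s absent: its features are reported missing", v)

    out = {}
    for name, (kind, view, keys) in FEATURE_DEFS.items():
        pts = world_views.get(view)
        if pts is None:
            out[name] = float("nan")
            continue
        resolved = [_resolve(k, pts) for k in keys]
        if any(p is None for p in resolved):
            out[name] = float("nan")
            continue
        if kind == "horiz":
            out[name] = angle_to_horizontal(*resolved)
        elif kind == "vertex":
            out[name] = angle_at_vertex(*resolved)
        elif kind == "lines":
            out[name] = angle_between_lines(*resolved, acute=acute_line_angles)
        elif kind == "dist":
            out[name] = distance_cm(*resolved)
        else:  # pragma: no cover
            raise RuntimeError(f"unknown primitive kind {kind}")
    return out


def is_distance_feature(name: str) -> bool:
    return name in DISTANCE_FEATURES
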