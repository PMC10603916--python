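"""Synthetic marker-scene rendering with exact ground truth.

The study images this package targets (a subject wearing green spherical
markers, a blue scale rectangle of known length on the left, a red plumb
string on the right) are emulated here: colored anti-aliased disks at
template-defined body positions, a filled rectangle and a thin
near-vertical line segment on a configurable background, plus Gaussian
pixel noise.  Every render returns the continuous ground-truth geometry
(disk centers, rectangle endpoints, plumb endpoints, cm-per-pixel scale,
plumb rotation) so downstream detection, calibration and labeling can be
tested without any real photographs.

Disks are rendered with analytic edge coverage; the ground-truth centroid
is the continuous disk center, not the rasterized centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import SceneSpecError
from .templates import PostureTemplate, default_template

#: named RGB colors used by the renderer (8-bit)
COLOR_TABLE = {
    "green": (40, 180, 70),
    "blue": (30, 80, 200),
    "red": (210, 40, 40),
    "white": (245, 245, 245),
    "gray": (150, 150, 150),
    "black": (25, 25, 25),
    "brown": (120, 80, 50),
}


def resolve_color(c) -> np.ndarray:
    if isinstance(c, str):
        try:
            return np.array(COLOR_TABLE[c], dtype=float)
        except KeyError:
            raise SceneSpecError(f"unknown color name {c!r}") from None
    arr = np.asarray(c, dtype=float)
    if arr.shape != (3,):
        raise SceneSpecError(f"color must be a name or RGB triple, got {c!r}")
    return arr


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic view.

    ``cm_per_px`` may be given explicitly; otherwise it is derived so the
    subject occupies ``subject_fraction`` of the image height.
    """

    template: PostureTemplate
    image_size: tuple = (1280, 960)          # (height, width) px
    subject_height_cm: float = 166.4
    marker_diameter_mm: float = 20.0
    marker_color: str = "green"
    rectangle_color: str = "blue"
    string_color: str = "red"
    background_color: str = "white"
    rectangle_length_cm: float = 20.0
    plumb_tilt_deg: float = 0.0
    noise_sd: float = 0.0
    occluded_sites: tuple = ()
    seed: int = 0
    cm_per_px: float | None = None
    subject_fraction: float = 0.82

    def __post_init__(self):
        if self.marker_diameter_mm <= 0:
            raise SceneSpecError("marker diameter must be positive")
        if self.rectangle_length_cm <= 0:
            raise SceneSpecError("rectangle length must be positive")
        extra = set(self.occluded_sites) - set(self.template.landmarks)
        if extra:
            raise SceneSpecError(
                f"occluded sites not in template: {sorted(extra)}")

    @property
    def scale_cm_per_px(self) -> float:
        if self.cm_per_px is not None:
            return float(self.cm_per_px)
        h_px = self.subject_fraction * self.image_size[0]
        return self.subject_height_cm / h_px


@dataclass(frozen=True)
class GroundTruth:
    """Continuous geometry behind a rendered scene."""

    centroids_px: dict                       # site -> (x, y)
    rectangle_endpoints_px: tuple            # ((x,y), (x,y)) of the long axis
    rectangle_length_px: float
    plumb_endpoints_px: tuple
    cm_per_px: float
    rotation_deg: float                      # plumb tilt from image vertical
    marker_radius_px: float = field(default=0.0)


# ---------------------------------------------------------------------------
# analytic-coverage rasterization helpers (image is float RGB, HxWx3)

def _blend(img, alpha, color, y0, x0):
    h, w = alpha.shape
    sl = img[y0:y0 + h, x0:x0 + w]
    sl *= (1.0 - alpha[..., None])
    sl += alpha[..., None] * color


def _draw_disk(img, cx, cy, r, color):
    h, w = img.shape[:2]
    x0 = max(int(math.floor(cx - r - 2)), 0)
    x1 = min(int(math.ceil(cx + r + 2)), w - 1)
    y0 = max(int(math.floor(cy - r - 2)), 0)
    y1 = min(int(math.ceil(cy + r + 2)), h - 1)
    if x1 < x0 or y1 < y0:
        return
    ys, xs = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    d = np.hypot(xs - cx, ys - cy)
    alpha = np.clip(r + 0.5 - d, 0.0, 1.0)
    _blend(img, alpha, color, y0, x0)


def _draw_axis_rect(img, x0f, x1f, y0f, y1f, color):
    h, w = img.shape[:2]
    x0 = max(int(math.floor(x0f - 1)), 0)
    x1 = min(int(math.ceil(x1f + 1)), w - 1)
    y0 = max(int(math.floor(y0f - 1)), 0)
    y1 = min(int(math.ceil(y1f + 1)), h - 1)
    ys, xs = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    covx = np.clip(np.minimum(x1f, xs + 0.5) - np.maximum(x0f, xs - 0.5), 0, 1)
    covy = np.clip(np.minimum(y1f, ys + 0.5) - np.maximum(y0f, ys - 0.5), 0, 1)
    _blend(img, covx * covy, color, y0, x0)


def _draw_segment(img, p0, p1, halfwidth, color):
    h, w = img.shape[:2]
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    lo = np.floor(np.minimum(p0, p1) - halfwidth - 2).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + halfwidth + 2).astype(int)
    x0, y0 = max(lo[0], 0), max(lo[1], 0)
    x1, y1 = min(hi[0], w - 1), min(hi[1], h - 1)
    ys, xs = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    v = p1 - p0
    L2 = float(v @ v)
    px = xs - p0[0]
    py = ys - p0[1]
    t = np.clip((px * v[0] + py * v[1]) / L2, 0.0, 1.0) if L2 > 0 else 0.0
    d = np.hypot(px - t * v[0], py - t * v[1])
    alpha = np.clip(halfwidth + 0.5 - d, 0.0, 1.0)
    _blend(img, alpha, color, y0, x0)


# ---------------------------------------------------------------------------

def render_view(spec: SceneSpec):
    """Render one view; returns ``(image_uint8_rgb, GroundTruth)``.

    The same spec (including seed) renders bit-identically.
    """
    H, W = spec.image_size
    s = spec.scale_cm_per_px
    r_px = (spec.marker_diameter_mm / 10.0) / s / 2.0
    if 2 * r_px < 3.0:
        raise SceneSpecError(
            f"marker renders at {2 * r_px:.2f} px diameter (< 3 px); "
            "increase resolution or marker size")

    img = np.empty((H, W, 3), dtype=float)
    img[:] = resolve_color(spec.background_color)

    h_px = spec.subject_height_cm / s
    cx = 0.5 * W
    y_bottom = 0.93 * H

    # scale rectangle, vertical on the left side of the image
    rect_len_px = spec.rectangle_length_cm / s
    rect_w_px = 0.25 * rect_len_px
    rx = 0.13 * W
    ry = 0.45 * H
    _draw_axis_rect(img, rx - rect_w_px / 2, rx + rect_w_px / 2,
                    ry - rect_len_px / 2, ry + rect_len_px / 2,
                    resolve_color(spec.rectangle_color))
    rect_eps = ((rx, ry - rect_len_px / 2), (rx, ry + rect_len_px / 2))

    # plumb line on the right, tilted from the image vertical
    th = math.radians(spec.plumb_tilt_deg)
    plumb_len = 0.8 * H
    top = np.array([0.87 * W - 0.5 * plumb_len * math.sin(th), 0.10 * H])
    bot = top + plumb_len * np.array([math.sin(th), math.cos(th)])
    _draw_segment(img, top, bot, 1.5, resolve_color(spec.string_color))

    # markers
    lm_img = spec.template.image_frame_landmarks()
    centroids = {}
    mcol = resolve_color(spec.marker_color)
    for site, (xn, yn) in lm_img.items():
        px = cx + (xn - 0.5) * h_px
        py = y_bottom - (1.0 - yn) * h_px
        if site in spec.occluded_sites:
            continue
        _draw_disk(img, px, py, r_px, mcol)
        centroids[site] = (px, py)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    gt = GroundTruth(
        centroids_px=centroids,
        rectangle_endpoints_px=rect_eps,
        rectangle_length_px=rect_len_px,
        plumb_endpoints_px=(tuple(top), tuple(bot)),
        cm_per_px=spec.rectangle_length_cm / rect_len_px,
        rotation_deg=spec.plumb_tilt_deg,
        marker_radius_px=r_px,
    )
    return img, gt


def neutral_scene(view: str = "anterior", **kwargs) -> SceneSpec:
    """Convenience: a SceneSpec for the neutral default template."""
    return SceneSpec(template=default_template(view), **kwargs)
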