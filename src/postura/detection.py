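"""Color thresholding and shape-filtered blob detection.

Marker candidates are isolated by an HSV threshold, grouped into
8-connected components, and filtered on four shape descriptors:

* area — polygon area of the outer contour (px²),
* circularity — ``4π·area / perimeter²`` (1 for a circle),
* convexity — area over convex-hull area,
* inertia ratio — minor/major principal-axis length ratio, the square
  root of the ratio of the second-central-moment eigenvalues of the
  pixel set (1 for a circle, →0 for a line).

The same machinery finds the blue scale rectangle (the largest qualifying
low-circularity component) and the red plumb string (the most elongated
qualifying component).  Hue is expressed in degrees on the 0–360 circle;
red may carry two hue intervals to handle the wraparound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage.color import rgb2hsv

from .errors import (
    AmbiguousScaleError, PlumbLineNotFoundError, ScaleNotFoundError,
)

# ---------------------------------------------------------------------------
# color specification and thresholding


@dataclass(frozen=True)
class ColorSpec:
    """HSV threshold ranges.  Hue in degrees [0, 360); one or two
    intervals (two for red wraparound).  Saturation/value in [0, 1]."""

    name: str
    hue_ranges: tuple
    s_range: tuple = (0.30, 1.0)
    v_range: tuple = (0.30, 1.0)

    def __post_init__(self):
        if not 1 <= len(self.hue_ranges) <= 2:
            raise ValueError("one or two hue intervals required")
        for lo, hi in self.hue_ranges:
            if not (0 <= lo <= hi <= 360):
                raise ValueError(f"hue interval out of bounds: {(lo, hi)}")
        for lo, hi in (self.s_range, self.v_range):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("saturation/value ranges must lie in [0,1]")


#: default color windows for the three in-scene references
DEFAULT_COLORS = {
    "green": ColorSpec("green", ((80.0, 160.0),)),
    "blue": ColorSpec("blue", ((200.0, 260.0),)),
    "red": ColorSpec("red", ((0.0, 20.0), (340.0, 360.0))),
}


def threshold_color(image: np.ndarray, color: ColorSpec) -> np.ndarray:
    """Binary mask of pixels whose HSV color falls in the spec's ranges."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    hsv = rgb2hsv(image)
    hue = hsv[..., 0] * 360.0
    mask = np.zeros(hue.shape, dtype=bool)
    for lo, hi in color.hue_ranges:
        mask |= (hue >= lo) & (hue <= hi)
    mask &= (hsv[..., 1] >= color.s_range[0]) & (hsv[..., 1] <= color.s_range[1])
    mask &= (hsv[..., 2] >= color.v_range[0]) & (hsv[..., 2] <= color.v_range[1])
    return mask


# ---------------------------------------------------------------------------
# shape descriptors


@dataclass(frozen=True)
class ShapeDescriptors:
    area: float
    perimeter: float
    circularity: float
    convexity: float
    inertia_ratio: float


@dataclass(frozen=True)
class Blob:
    centroid: tuple          # (x, y) px, unweighted pixel centroid
    area: float
    perimeter: float
    circularity: float
    convexity: float
    inertia_ratio: float


@dataclass(frozen=True)
class BlobFilterParams:
    """Bounds on the four descriptors.  Defaults accept a rendered 20 mm
    spherical marker over typical acquisition distances and reject the
    scale rectangle and the plumb string."""

    min_area: float = 80.0
    max_area: float = 8000.0
    min_circularity: float = 0.6
    max_circularity: float = 1.0
    min_convexity: float = 0.85
    max_convexity: float = 1.0
    min_inertia_ratio: float = 0.4
    max_inertia_ratio: float = 1.0

    def __post_init__(self):
        for lo, hi, what in (
            (self.min_area, self.max_area, "area"),
            (self.min_circularity, self.max_circularity, "circularity"),
            (self.min_convexity, self.max_convexity, "convexity"),
            (self.min_inertia_ratio, self.max_inertia_ratio, "inertia ratio"),
        ):
            if lo > hi:
                raise ValueError(f"min {what} exceeds max {what}")
        for v in (self.min_circularity, self.max_circularity,
                  self.min_convexity, self.max_convexity,
                  self.min_inertia_ratio, self.max_inertia_ratio):
            if not 0.0 <= v <= 1.0:
                raise ValueError("descriptor bounds must lie in [0, 1]")


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def shape_descriptors(contour: np.ndarray, pixels: np.ndarray) -> ShapeDescriptors:
    """Descriptors from an outer contour polygon and the component's
    pixel set.

    ``contour`` is an (N, 2) array of (x, y) vertices of the outer
    boundary (subpixel, closed implicitly); ``pixels`` an (M, 2) integer
    array of (x, y) pixel centers.  Circularity/convexity use the contour
    geometry; the inertia ratio uses the second central moments of the
    pixel set.  All unit-interval descriptors are clamped to [0, 1] —
    a digitized circle can rationally exceed 1 by a rasterization hair.
    """
    contour = np.asarray(contour, dtype=float)
    pixels = np.asarray(pixels, dtype=float)
    if len(contour) < 3:
        raise ValueError("contour needs at least 3 boundary points")

    area = _polygon_area(contour)
    diffs = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    perimeter = float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())

    circularity = 4.0 * math.pi * area / perimeter ** 2 if perimeter > 0 else 0.0

    try:
        hull_area = float(ConvexHull(contour).volume)
    except QhullError:  # collinear contour
        hull_area = 0.0
    convexity = area / hull_area if hull_area > 0 else 1.0

    centered = pixels - pixels.mean(axis=0)
    cov = centered.T @ centered / len(pixels)
    eig = np.linalg.eigvalsh(cov)
    lam_min, lam_max = float(eig[0]), float(eig[1])
    inertia = math.sqrt(max(lam_min, 0.0) / lam_max) if lam_max > 0 else 0.0

    clamp = lambda v: min(max(v, 0.0), 1.0)
    return ShapeDescriptors(
        area=area,
        perimeter=perimeter,
        circularity=clamp(circularity),
        convexity=clamp(convexity),
        inertia_ratio=clamp(inertia),
    )


# ---------------------------------------------------------------------------
# connected components

@dataclass(frozen=True)
class _Component:
    centroid: tuple
    contour: np.ndarray      # (x, y) vertices
    pixels: np.ndarray       # (x, y) integer centers
    desc: ShapeDescriptors


def _outer_contour(region_mask: np.ndarray) -> np.ndarray:
    """Subpixel outer contour (marching squares at level 0.5) of a padded
    component mask, returned as (x, y) vertices.  Diagonal boundary steps
    contribute their Euclidean length, which keeps the perimeter of a
    digitized circle close to 2πr."""
    padded = np.pad(region_mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    outer = max(contours, key=lambda c: _polygon_area(c))
    # straighten the marching-squares staircase: without this the
    # perimeter of a digitized circle overestimates 2*pi*r by ~6%
    approx = measure.approximate_polygon(outer, tolerance=1.0)
    if len(approx) >= 4:
        outer = approx
    # rows/cols -> x/y, undo padding offset
    return np.column_stack([outer[:, 1] - 1.0, outer[:, 0] - 1.0])


def find_components(mask: np.ndarray, min_pixels: int = 3) -> list:
    """All 8-connected components of a binary mask with descriptors,
    ordered by (y, x) of centroid.  Components touching the border are
    kept."""
    labels = measure.label(mask, connectivity=2)
    comps = []
    for region in measure.regionprops(labels):
        if region.num_pixels < min_pixels:
            continue
        rr0, cc0, _, _ = region.bbox
        local = _outer_contour(region.image)
        contour = local + np.array([cc0, rr0], dtype=float)
        pix = np.column_stack([region.coords[:, 1], region.coords[:, 0]])
        desc = shape_descriptors(contour, pix)
        cx, cy = pix[:, 0].mean(), pix[:, 1].mean()
        comps.append(_Component((float(cx), float(cy)), contour, pix, desc))
    comps.sort(key=lambda c: (c.centroid[1], c.centroid[0]))
    return comps


def detect_blobs(mask: np.ndarray, params: BlobFilterParams | None = None) -> list:
    """Blobs passing all four shape filters, ordered by (y, x)."""
    params = params or BlobFilterParams()
    out = []
    for comp in find_components(mask):
        d = comp.desc
        if not (params.min_area <= d.area <= params.max_area):
            continue
        if not (params.min_circularity <= d.circularity <= params.max_circularity):
            continue
        if not (params.min_convexity <= d.convexity <= params.max_convexity):
            continue
        if not (params.min_inertia_ratio <= d.inertia_ratio <= params.max_inertia_ratio):
            continue
        out.append(Blob(comp.centroid, d.area, d.perimeter, d.circularity,
                        d.convexity, d.inertia_ratio))
    return out


# ---------------------------------------------------------------------------
# scale rectangle


@dataclass(frozen=True)
class RectangleParams:
    min_area: float = 300.0
    max_circularity: float = 0.85
    ambiguity_ratio: float = 0.9  # 2nd candidate within this area fraction


@dataclass(frozen=True)
class RectangleObservation:
    center: tuple
    endpoints: tuple          # two (x, y) midpoints of the short sides
    length_px: float


def _min_rotated_rect(contour: np.ndarray):
    from shapely.geometry import MultiPoint

    rect = MultiPoint([tuple(p) for p in contour]).minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)[:4]
    sides = [(coords[i], coords[(i + 1) % 4]) for i in range(4)]
    lengths = [float(np.hypot(*(b - a))) for a, b in sides]
    i_long = int(np.argmax(lengths))
    # endpoints = midpoints of the two short sides adjacent to the long one
    a0, b0 = sides[(i_long + 1) % 4]
    a1, b1 = sides[(i_long + 3) % 4]
    e0 = (a0 + b0) / 2.0
    e1 = (a1 + b1) / 2.0
    return lengths[i_long], (tuple(e0), tuple(e1)), tuple(coords.mean(axis=0))


def detect_scale_rectangle(image: np.ndarray,
                           color: ColorSpec | None = None,
                           params: RectangleParams | None = None) -> RectangleObservation:
    """Locate the scale rectangle: the single largest low-circularity
    component of the rectangle color."""
    color = color or DEFAULT_COLORS["blue"]
    params = params or RectangleParams()
    mask = threshold_color(image, color)
    qualifying = [c for c in find_components(mask)
                  if c.desc.area >= params.min_area
                  and c.desc.circularity <= params.max_circularity]
    if not qualifying:
        raise ScaleNotFoundError("scale reference not found")
    qualifying.sort(key=lambda c: -c.desc.area)
    if (len(qualifying) > 1
            and qualifying[1].desc.area >= params.ambiguity_ratio * qualifying[0].desc.area):
        raise AmbiguousScaleError([c.desc.area for c in qualifying[:2]])
    best = qualifying[0]
    length, endpoints, center = _min_rotated_rect(best.contour)
    if length <= 0:
        raise ScaleNotFoundError("scale reference degenerate")
    return RectangleObservation(center=center, endpoints=endpoints, length_px=length)


# ---------------------------------------------------------------------------
# plumb line


@dataclass(frozen=True)
class PlumbParams:
    min_area: float = 50.0
    max_inertia_ratio: float = 0.2


@dataclass(frozen=True)
class PlumbLineObservation:
    direction: tuple          # unit vector, y-component >= 0 (image down)
    endpoints: tuple
    elongation: float         # the component's inertia ratio


def detect_plumb_line(image: np.ndarray,
                      color: ColorSpec | None = None,
                      params: PlumbParams | None = None) -> PlumbLineObservation:
    """Locate the plumb string: the most elongated qualifying component of
    the string color.  With a red background the string merges with the
    wall into a non-elongated blob, and this raises
    :class:`PlumbLineNotFoundError`."""
    color = color or DEFAULT_COLORS["red"]
    params = params or PlumbParams()
    mask = threshold_color(image, color)
    qualifying = [c for c in find_components(mask)
                  if c.desc.area >= params.min_area
                  and c.desc.inertia_ratio <= params.max_inertia_ratio]
    if not qualifying:
        raise PlumbLineNotFoundError("plumb line not found")
    best = min(qualifying, key=lambda c: c.desc.inertia_ratio)

    pix = best.pixels.astype(float)
    centered = pix - pix.mean(axis=0)
    cov = centered.T @ centered / len(pix)
    w, v = np.linalg.eigh(cov)
    axis = v[:, int(np.argmax(w))]
    if axis[1] < 0:
        axis = -axis
    proj = centered @ axis
    p0 = pix.mean(axis=0) + proj.min() * axis
    p1 = pix.mean(axis=0) + proj.max() * axis
    return PlumbLineObservation(direction=(float(axis[0]), float(axis[1])),
                                endpoints=(tuple(p0), tuple(p1)),
                                elongation=best.desc.inertia_ratio)
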