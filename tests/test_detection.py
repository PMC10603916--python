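"""Color thresholding, shape descriptors and the three detectors.

The descriptor checks use independent brute-force computations written
here (explicit shoelace loop, monotone-chain hull, closed-form 2x2
eigendecomposition) against the package's vectorized/library paths.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from postura.detection import (
    Blob, BlobFilterParams, ColorSpec, DEFAULT_COLORS, detect_blobs,
    detect_plumb_line, detect_scale_rectangle, find_components,
    shape_descriptors, threshold_color,
)
from postura.errors import (
    AmbiguousScaleError, PlumbLineNotFoundError, ScaleNotFoundError,
)
from postura.scene import COLOR_TABLE, SceneSpec, render_view
from postura.templates import default_template

GREEN = np.array(COLOR_TABLE["green"], dtype=np.uint8)


def solid(color, shape=(50, 50)):
    img = np.zeros(shape + (3,), dtype=np.uint8)
    img[:] = color
    return img


# ---------------------------------------------------------------------------
# thresholding


def test_uniform_green_image_fully_masked():
    mask = threshold_color(solid(GREEN), DEFAULT_COLORS["green"])
    assert mask.all()


def test_green_disk_pixel_count_near_area():
    img = solid((245, 245, 245), (120, 120))
    yy, xx = np.mgrid[0:120, 0:120]
    disk = (xx - 60) ** 2 + (yy - 60) ** 2 <= 20 ** 2
    img[disk] = GREEN
    mask = threshold_color(img, DEFAULT_COLORS["green"])
    assert mask.sum() == pytest.approx(math.pi * 400, rel=0.03)


def test_red_on_red_masks_nearly_whole_frame():
    img, _ = render_view(SceneSpec(template=default_template("anterior"),
                                   background_color="red"))
    mask = threshold_color(img, DEFAULT_COLORS["red"])
    assert mask.mean() > 0.9


def test_mask_idempotence():
    img, _ = render_view(SceneSpec(template=default_template("anterior"),
                                   seed=2, noise_sd=1.0))
    mask = threshold_color(img, DEFAULT_COLORS["green"])
    remasked = img.copy()
    remasked[~mask] = 0  # black fails the value threshold
    mask2 = threshold_color(remasked, DEFAULT_COLORS["green"])
    assert np.array_equal(mask2, mask)


def test_colorspec_validation():
    with pytest.raises(ValueError):
        ColorSpec("bad", ((-5.0, 10.0),))
    with pytest.raises(ValueError):
        ColorSpec("bad", ((0.0, 10.0),), s_range=(0.5, 1.5))
    with pytest.raises(ValueError):
        ColorSpec("bad", ())


# ---------------------------------------------------------------------------
# shape descriptors vs brute force


def _brute_shoelace(pts):
    area = 0.0
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def _brute_perimeter(pts):
    total = 0.0
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        total += math.hypot(x2 - x1, y2 - y1)
    return total


def _brute_hull(points):
    """Andrew monotone chain; returns hull vertices CCW."""
    pts = sorted(set(map(tuple, points)))
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def _brute_inertia(pixels):
    xs = [p[0] for p in pixels]
    ys = [p[1] for p in pixels]
    mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
    sxx = sum((x - mx) ** 2 for x in xs) / len(xs)
    syy = sum((y - my) ** 2 for y in ys) / len(ys)
    sxy = sum((x - mx) * (y - my) for x, y in pixels) / len(pixels)
    tr, det = sxx + syy, sxx * syy - sxy * sxy
    disc = math.sqrt(max(tr * tr / 4 - det, 0.0))
    lam1, lam2 = tr / 2 + disc, tr / 2 - disc
    return math.sqrt(max(lam2, 0.0) / lam1) if lam1 > 0 else 0.0


def _random_convex_polygon(rng, n_max=10):
    n = rng.integers(4, n_max + 1)
    pts = rng.uniform(0, 100, (30, 2))
    hull = _brute_hull(pts)
    while len(hull) > n:
        hull.pop(rng.integers(0, len(hull)))
    return np.array(_brute_hull(hull), dtype=float)


def test_descriptors_match_brute_force_on_200_random_convex_polygons():
    rng = np.random.default_rng(42)
    for _ in range(200):
        poly = _random_convex_polygon(rng)
        if len(poly) < 3:
            continue
        pixels = np.round(rng.uniform(0, 100, (60, 2))).astype(int)
        d = shape_descriptors(poly, pixels)
        area = _brute_shoelace(poly)
        perim = _brute_perimeter(poly)
        hull_area = _brute_shoelace(_brute_hull(poly))
        assert d.area == pytest.approx(area, abs=1e-6)
        assert d.circularity == pytest.approx(
            min(4 * math.pi * area / perim ** 2, 1.0), abs=1e-6)
        assert d.convexity == pytest.approx(
            min(area / hull_area, 1.0), abs=1e-6)
        assert d.inertia_ratio == pytest.approx(
            _brute_inertia([tuple(p) for p in pixels]), abs=1e-6)


def test_digitized_circle_descriptor_limits():
    yy, xx = np.mgrid[0:140, 0:140]
    mask = (xx - 70) ** 2 + (yy - 70) ** 2 <= 50 ** 2
    d = find_components(mask)[0].desc
    assert d.circularity >= 0.95
    assert d.inertia_ratio >= 0.95
    assert d.convexity >= 0.98


def test_square_circularity_near_closed_form():
    mask = np.zeros((80, 80), dtype=bool)
    mask[20:60, 20:60] = True
    d = find_components(mask)[0].desc
    assert d.circularity == pytest.approx(math.pi / 4, abs=0.05)


def test_elongated_bar_inertia_ratio():
    mask = np.zeros((40, 140), dtype=bool)
    mask[15:25, 20:120] = True
    d = find_components(mask)[0].desc
    assert d.inertia_ratio == pytest.approx(0.1, abs=0.02)


def test_one_pixel_wide_component_degenerates_to_zero_inertia():
    mask = np.zeros((20, 60), dtype=bool)
    mask[10, 5:55] = True
    d = find_components(mask)[0].desc
    assert d.inertia_ratio == 0.0


# ---------------------------------------------------------------------------
# blob filtering


def _three_disk_mask():
    mask = np.zeros((100, 300), dtype=bool)
    yy, xx = np.mgrid[0:100, 0:300]
    truth = []
    for cx in (50, 150, 250):
        mask |= (xx - cx) ** 2 + (yy - 50) ** 2 <= 10 ** 2
        truth.append((cx, 50))
    return mask, truth


def test_three_disks_detected_with_accurate_centroids():
    mask, truth = _three_disk_mask()
    blobs = detect_blobs(mask, BlobFilterParams(min_area=200, max_area=500,
                                                min_circularity=0.0,
                                                min_convexity=0.0,
                                                min_inertia_ratio=0.0))
    assert len(blobs) == 3
    for b, (cx, cy) in zip(blobs, truth):
        assert math.hypot(b.centroid[0] - cx, b.centroid[1] - cy) <= 0.5


def test_area_filter_excludes_small_disk():
    mask, _ = _three_disk_mask()
    blobs = detect_blobs(mask, BlobFilterParams(min_area=400, max_area=1e5,
                                                min_circularity=0.0,
                                                min_convexity=0.0,
                                                min_inertia_ratio=0.0))
    assert blobs == []


def test_inertia_filter_on_bar():
    mask = np.zeros((40, 140), dtype=bool)
    mask[15:25, 20:120] = True
    base = dict(min_area=100, max_area=1e5, min_circularity=0.0,
                min_convexity=0.0)
    assert detect_blobs(mask, BlobFilterParams(**base,
                                               min_inertia_ratio=0.4)) == []
    assert len(detect_blobs(mask, BlobFilterParams(
        **base, min_inertia_ratio=0.05))) == 1


def test_blob_ordering_is_deterministic_by_y_then_x():
    mask = np.zeros((100, 100), dtype=bool)
    yy, xx = np.mgrid[0:100, 0:100]
    for cx, cy in ((70, 20), (30, 20), (50, 70)):
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= 8 ** 2
    blobs = detect_blobs(mask, BlobFilterParams(min_area=50, max_area=1e4,
                                                min_circularity=0,
                                                min_convexity=0,
                                                min_inertia_ratio=0))
    cents = [b.centroid for b in blobs]
    assert cents == sorted(cents, key=lambda c: (c[1], c[0]))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.sampled_from(["min_area", "min_circularity", "min_convexity",
                        "min_inertia_ratio"]),
       st.floats(min_value=0.0, max_value=1.0))
def test_loosening_one_bound_never_decreases_blob_count(field_name, frac):
    mask, _ = _three_disk_mask()
    tight = BlobFilterParams(min_area=250, max_area=400, min_circularity=0.7,
                             min_convexity=0.9, min_inertia_ratio=0.6)
    loose_val = getattr(tight, field_name) * frac
    loose = BlobFilterParams(**{**tight.__dict__, field_name: loose_val})
    assert len(detect_blobs(mask, loose)) >= len(detect_blobs(mask, tight))


def test_filter_params_validation():
    with pytest.raises(ValueError):
        BlobFilterParams(min_area=10, max_area=5)
    with pytest.raises(ValueError):
        BlobFilterParams(min_circularity=1.2)


# ---------------------------------------------------------------------------
# scale rectangle


def test_rendered_rectangle_length_within_one_percent():
    img = solid((245, 245, 245), (600, 600))
    img[100:180, 80:480] = COLOR_TABLE["blue"]  # 400 x 80
    obs = detect_scale_rectangle(img)
    assert obs.length_px == pytest.approx(400, rel=0.01)


def test_no_blue_raises_scale_not_found():
    with pytest.raises(ScaleNotFoundError, match="not found"):
        detect_scale_rectangle(solid((245, 245, 245)))


def test_two_equal_rectangles_are_ambiguous():
    img = solid((245, 245, 245), (600, 600))
    img[50:90, 50:450] = COLOR_TABLE["blue"]
    img[500:540, 50:450] = COLOR_TABLE["blue"]
    with pytest.raises(AmbiguousScaleError):
        detect_scale_rectangle(img)


# ---------------------------------------------------------------------------
# plumb line


def _line_image(tilt_deg, shape=(600, 400)):
    img = solid((245, 245, 245), shape)
    from postura.scene import _draw_segment
    fimg = img.astype(float)
    th = math.radians(tilt_deg)
    top = np.array([200.0 - 250 * math.sin(th), 50.0])
    bot = top + 500 * np.array([math.sin(th), math.cos(th)])
    _draw_segment(fimg, top, bot, 1.0, np.array(COLOR_TABLE["red"], float))
    return np.clip(np.rint(fimg), 0, 255).astype(np.uint8)


def test_tilted_line_direction_recovered_within_02_degrees():
    obs = detect_plumb_line(_line_image(2.0))
    ang = math.degrees(math.atan2(obs.direction[0], obs.direction[1]))
    assert ang == pytest.approx(2.0, abs=0.2)


def test_vertical_line_direction_is_straight_down():
    obs = detect_plumb_line(_line_image(0.0))
    assert obs.direction[0] == pytest.approx(0.0, abs=1e-3)
    assert obs.direction[1] == pytest.approx(1.0, abs=1e-6)
    assert obs.elongation <= 0.2


def test_red_background_scene_has_no_plumb_line():
    img, _ = render_view(SceneSpec(template=default_template("anterior"),
                                   background_color="red"))
    with pytest.raises(PlumbLineNotFoundError, match="plumb line not found"):
        detect_plumb_line(img)
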