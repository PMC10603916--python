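"""Blob → anatomical-site assignment and manual overrides.

Detected marker blobs carry no identity; this module labels them by
matching the blob cloud against the view's posture template.  Both
clouds are first normalized robustly (median center, median pairwise
distance scale) and matched by an exact optimal assignment on the
squared-distance cost matrix; a trimmed per-axis linear map into the
template's unit bounding box is then fitted on the best-matching pairs
and the assignment re-solved in that space, where the rejection
threshold applies.  The robust normalization and the trimmed refit keep
the labeling stable against occluded extreme markers and far-outlier
false detections.

Matches whose residual cost exceeds the rejection threshold are dropped:
their sites are flagged missing and their blobs reported as surplus,
rather than silently mislabeled.  If fewer than half the sites can be
matched plausibly the whole configuration is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .calibration import Calibration, to_world
from .detection import Blob
from .errors import ImplausibleConfigurationError, InsufficientMarkersError
from .sites import VIEW_MIRRORED, VIEW_SITES
from .templates import PostureTemplate

DETECTED = "detected"
MANUAL = "manual"
MISSING = "missing"


@dataclass(frozen=True)
class LandmarkSet:
    """Per-view mapping of anatomical sites to pixel points."""

    view: str
    points: dict                       # site -> (x, y) px; absent if missing
    provenance: dict                   # site -> detected | manual | missing
    surplus_blobs: tuple = ()          # centroids of unassigned blobs

    def missing_sites(self) -> list:
        return sorted(s for s, p in self.provenance.items() if p == MISSING)

    def world_points(self, cal: Calibration) -> dict:
        """Calibrated world coordinates with +x toward the subject's
        anatomical right (the anterior view is mirrored)."""
        mirror = VIEW_MIRRORED[self.view]
        out = {}
        for site, p in self.points.items():
            w = to_world(p, cal)
            if mirror:
                w = np.array([-w[0], w[1]])
            out[site] = w
        return out


def _normalize(pts: np.ndarray):
    """Center on the coordinate-wise median and scale by the median
    pairwise distance — robust to a few far-outlier blobs that would
    wreck a bounding-box normalization."""
    med = np.median(pts, axis=0)
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    iu = np.triu_indices(len(pts), k=1)
    scale = float(max(np.median(d[iu]), 1e-12))
    return (pts - med) / scale


def assign_landmarks(blobs: list, view: str, template: PostureTemplate,
                     rejection_threshold: float = 0.01) -> LandmarkSet:
    """Label blobs with site names by optimal template matching.

    ``rejection_threshold`` is the maximum tolerated normalized squared
    distance, both per matched pair and as the mean over kept pairs.
    """
    sites = list(VIEW_SITES[view])
    if len(blobs) < 3:
        raise InsufficientMarkersError(
            f"{len(blobs)} blobs detected in {view}; at least 3 required")

    tpl_img = template.image_frame_landmarks()
    tpl_sites = [s for s in sites if s in tpl_img]
    t_pts = np.array([tpl_img[s] for s in tpl_sites], dtype=float)
    b_pts = np.array([b.centroid for b in blobs], dtype=float)

    # template-bbox space: the unit in which the rejection threshold lives
    t_lo = t_pts.min(axis=0)
    t_span = float(max((t_pts.max(axis=0) - t_lo).max(), 1e-12))
    t_n = (t_pts - t_lo) / t_span
    t_r = _normalize(t_pts)

    def assign(cost):
        rows, cols = linear_sum_assignment(cost)
        return rows, cols

    def assign_gated(cost):
        """Assignment in template-bbox space with opt-out: dummy columns
        at the rejection threshold let an implausible blob go unassigned
        instead of displacing a good match."""
        n_b = cost.shape[0]
        aug = np.hstack([cost, np.full((n_b, n_b), rejection_threshold)])
        rows, cols = linear_sum_assignment(aug)
        real = cols < cost.shape[1]
        return rows[real], cols[real]

    def refit(sub, rows, cols):
        """Per-axis linear map blob px -> template-bbox space fitted on
        matched pairs; returns the re-solved assignment and cost."""
        A = np.column_stack([sub[rows], np.ones(len(rows))])
        b_t = np.empty_like(sub)
        for axis in range(2):
            coef, *_ = np.linalg.lstsq(A[:, [axis, 2]], t_n[cols, axis],
                                       rcond=None)
            b_t[:, axis] = sub[:, axis] * coef[0] + coef[1]
        cost = ((b_t[:, None, :] - t_n[None, :, :]) ** 2).sum(axis=2)
        rows, cols = assign_gated(cost)
        return rows, cols, cost

    def solve(inliers):
        """Assignment of the inlier blobs: robust-space match, then a
        trimmed linear refit into template-bbox space (where the
        rejection threshold applies), then a clean second refit."""
        sub = b_pts[inliers]
        b_r = _normalize(sub)
        cost0 = ((b_r[:, None, :] - t_r[None, :, :]) ** 2).sum(axis=2)
        rows, cols = assign(cost0)
        if len(rows) < 3:
            return rows, cols, cost0
        # trimmed fit: only the best-matching half of the pairs, so a
        # few grossly mismatched blobs cannot drag the map
        order = np.argsort(cost0[rows, cols])
        keep = order[:max(3, len(order) // 2 + 1)]
        rows, cols, cost = refit(sub, rows[keep], cols[keep])
        good = cost[rows, cols] <= rejection_threshold
        if good.sum() >= 3:
            rows, cols, cost = refit(sub, rows[good], cols[good])
        return rows, cols, cost

    # iterative trimming: drop rejected blobs (e.g. far outliers) and
    # re-fit on the survivors
    used = np.arange(len(b_pts))
    rows, cols, cost = solve(used)
    for _ in range(2):
        good = cost[rows, cols] <= rejection_threshold
        if good.all() or good.sum() < 3:
            break
        shrunk = used[rows[good]]
        if len(shrunk) == len(used):
            break
        used = shrunk
        rows, cols, cost = solve(used)

    # the trim only refined the map; the final assignment considers every
    # blob under the map fitted on the trusted pairs
    trusted = [(used[r], c) for r, c in zip(rows, cols)
               if cost[r, c] <= rejection_threshold]
    if len(trusted) >= 3:
        bidx = np.array([b for b, _ in trusted])
        cidx = np.array([c for _, c in trusted])
        A = np.column_stack([b_pts[bidx], np.ones(len(bidx))])
        b_t = np.empty_like(b_pts)
        for axis in range(2):
            coef, *_ = np.linalg.lstsq(A[:, [axis, 2]], t_n[cidx, axis],
                                       rcond=None)
            b_t[:, axis] = b_pts[:, axis] * coef[0] + coef[1]
        cost = ((b_t[:, None, :] - t_n[None, :, :]) ** 2).sum(axis=2)
        rows, cols = assign_gated(cost)
        used = np.arange(len(b_pts))

    kept = [(used[r], c) for r, c in zip(rows, cols)
            if cost[r, c] <= rejection_threshold]
    if len(kept) < max(3, (len(tpl_sites) + 1) // 2):
        raise ImplausibleConfigurationError(
            f"only {len(kept)} of {len(tpl_sites)} sites plausibly "
            f"matched in {view}")
    mean_cost = float(
        np.mean([d for d in cost[rows, cols] if d <= rejection_threshold]))
    if mean_cost > rejection_threshold:
        raise ImplausibleConfigurationError(
            f"mean normalized assignment cost {mean_cost:.4f} exceeds "
            f"threshold {rejection_threshold}")

    points, provenance = {}, {}
    matched_sites = set()
    matched_blobs = set()
    for bi, c in kept:
        site = tpl_sites[c]
        points[site] = tuple(map(float, b_pts[bi]))
        provenance[site] = DETECTED
        matched_sites.add(site)
        matched_blobs.add(int(bi))
    for site in sites:
        if site not in matched_sites:
            provenance[site] = MISSING
    surplus = tuple(tuple(map(float, b_pts[i]))
                    for i in range(len(blobs)) if i not in matched_blobs)
    return LandmarkSet(view=view, points=points, provenance=provenance,
                       surplus_blobs=surplus)


def apply_overrides(ls: LandmarkSet, overrides: dict) -> LandmarkSet:
    """Fill or replace landmarks with manually supplied pixel points."""
    if not overrides:
        return ls
    bad = set(overrides) - set(VIEW_SITES[ls.view])
    if bad:
        raise ValueError(
            f"override site(s) not in view {ls.view}: {sorted(bad)}")
    points = dict(ls.points)
    provenance = dict(ls.provenance)
    for site, p in overrides.items():
        points[site] = (float(p[0]), float(p[1]))
        provenance[site] = MANUAL
    return replace(ls, points=points, provenance=provenance)
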