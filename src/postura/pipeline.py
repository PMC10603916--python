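"""End-to-end processing: images → blobs → calibration → landmarks →
features, per subject and per study manifest.

``run_subject`` processes the available views of one subject and returns
the 38-feature vector plus per-view diagnostics; ``run_study`` iterates
a manifest (``subject_id,view,path``), collecting per-subject failures
without aborting the run.  Every study run can write a provenance record
(config hash, seed, package version) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .calibration import build_frame
from .config import PipelineConfig
from .detection import (
    detect_blobs, detect_plumb_line, detect_scale_rectangle, threshold_color,
)
from .errors import DetectionError, PosturaError, ViewProcessingError
from .landmarks import apply_overrides, assign_landmarks
from .metrics import compute_features
from .sites import FEATURE_NAMES, VIEWS
from .templates import default_template

logger = logging.getLogger(__name__)


def load_image(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


@dataclass
class ViewDiagnostics:
    view: str
    n_blobs: int = 0
    cm_per_px: float | None = None
    rotation_deg: float | None = None
    missing_sites: list = field(default_factory=list)
    surplus_blobs: int = 0
    error: str | None = None


def process_view(image: np.ndarray, view: str, config: PipelineConfig,
                 template=None, overrides: dict | None = None):
    """One view: detection, calibration, assignment.  Returns
    ``(world_points, diagnostics)``; raises ViewProcessingError on a
    stage failure."""
    template = template or default_template(view)
    diag = ViewDiagnostics(view=view)
    try:
        mask = threshold_color(image, config.colors[config.marker_color])
        blobs = detect_blobs(mask, config.blob_filters)
        diag.n_blobs = len(blobs)

        try:
            rect = detect_scale_rectangle(
                image, config.colors[config.rectangle_color],
                config.rectangle_params)
            plumb = detect_plumb_line(
                image, config.colors[config.string_color], config.plumb_params)
        except DetectionError as e:
            raise ViewProcessingError(
                view, "calibration", e,
                hint="check that the scale rectangle and the plumb string "
                     "contrast with the background (a red string on a red "
                     "wall cannot be segmented)") from e
        cal = build_frame(rect, plumb, config.scale_length_cm)
        diag.cm_per_px = cal.cm_per_px
        diag.rotation_deg = cal.rotation_deg

        ls = assign_landmarks(blobs, view, template,
                              config.rejection_threshold)
        if overrides:
            ls = apply_overrides(ls, overrides)
        diag.missing_sites = ls.missing_sites()
        diag.surplus_blobs = len(ls.surplus_blobs)
        return ls.world_points(cal), diag
    except ViewProcessingError:
        raise
    except PosturaError as e:
        raise ViewProcessingError(view, "processing", e) from e


def run_subject(images: dict, config: PipelineConfig | None = None,
                templates: dict | None = None,
                overrides: dict | None = None):
    """Process one subject's views.

    ``images`` maps view name → path or RGB array (at least one view).
    Returns ``(features, diagnostics)`` where features is the full
    38-name dict (NaN for features of absent views) and diagnostics a
    list of :class:`ViewDiagnostics`.
    """
    if not images:
        raise ValueError("at least one view must be supplied")
    bad = set(images) - set(VIEWS)
    if bad:
        raise ValueError(f"unknown view(s): {sorted(bad)}")
    config = config or PipelineConfig()
    world_views = {}
    diags = []
    for view, img in images.items():
        if isinstance(img, (str, Path)):
            img = load_image(img)
        tpl = (templates or {}).get(view)
        ov = (overrides or {}).get(view)
        pts, diag = process_view(img, view, config, tpl, ov)
        world_views[view] = pts
        diags.append(diag)
    for view in VIEWS:
        if view not in images:
            logger.warning("subject lacks view %s; its features are missing",
                           view)
    return compute_features(world_views, config.acute_line_angles), diags


def run_study(manifest: pd.DataFrame, config: PipelineConfig | None = None,
              image_root=None):
    """Process a study manifest with columns ``subject_id,view,path``.

    Per-subject failures are collected and the run continues; returns
    ``(feature_table, failures)`` with one feature row per successful
    subject.
    """
    config = config or PipelineConfig()
    required = {"subject_id", "view", "path"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    root = Path(image_root) if image_root else None
    rows, failures = [], {}
    for sid, grp in manifest.groupby("subject_id", sort=True):
        images = {}
        for _, r in grp.iterrows():
            p = Path(r["path"])
            if root and not p.is_absolute():
                p = root / p
            images[r["view"]] = p
        try:
            feats, _ = run_subject(images, config)
            rows.append({"subject_id": sid, **feats})
        except (PosturaError, OSError, ValueError) as e:
            failures[sid] = str(e)
            logger.error("subject %s failed: %s", sid, e)
    table = pd.DataFrame(rows, columns=["subject_id", *FEATURE_NAMES])
    return table, failures


def provenance_record(config: PipelineConfig) -> dict:
    cfg_yaml = config.to_yaml()
    return {
        "package": "postura",
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": config.seed,
    }


def write_provenance(config: PipelineConfig, outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "provenance.json"
    path.write_text(json.dumps(provenance_record(config), indent=2))
    return path
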