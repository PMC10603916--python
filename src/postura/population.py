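"""Labeled synthetic feature populations for classifier development.

Subjects are simulated by sampling posture-deformation parameters from
class-conditional distributions, deforming the neutral four-view
template, computing the 38 features geometrically, and adding
independent measurement noise.  Severity classes are ordered: ``none``
has zero deformation, ``mild`` a small pelvic obliquity and shoulder
drop (2–4°), ``moderate_severe`` a large one (6–10°) plus a kyphosis
gain and a frontal-plane spinal offset.

The defaults mirror the screening-study composition this package
emulates: 16 / 25 / 16 subjects for none / mild / moderate-to-severe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import compute_features
from .sites import FEATURE_NAMES, VIEWS
from .templates import PERTURBATION_NAMES, Perturbations, default_template

LABELS = ("none", "mild", "moderate_severe")

#: study-population class sizes
DEFAULT_CLASS_COUNTS = {"none": 16, "mild": 25, "moderate_severe": 16}

#: class-conditional (mean, sd) of each nonzero deformation parameter
DEFAULT_CLASS_EFFECTS = {
    "none": {},
    "mild": {
        "pelvic_obliquity_deg": (3.0, 0.7),
        "shoulder_drop_deg": (-2.5, 0.7),
    },
    "moderate_severe": {
        "pelvic_obliquity_deg": (8.0, 1.2),
        "shoulder_drop_deg": (-6.0, 1.2),
        "kyphosis_gain": (1.0, 0.2),
        "scoliosis_offset": (0.04, 0.01),
    },
}

#: measurement noise added to every feature (deg or cm)
DEFAULT_NOISE_SD = 0.5


def subject_features(perturbations: Perturbations | dict,
                     subject_height_cm: float = 166.4) -> dict:
    """Noise-free features of one simulated subject."""
    world_views = {}
    for view in VIEWS:
        tpl = default_template(view).perturbed(perturbations)
        world_views[view] = tpl.world_landmarks_cm(subject_height_cm)
    return compute_features(world_views)


def make_feature_population(n_per_class: dict | None = None,
                            effects: dict | None = None,
                            noise_sd: float = DEFAULT_NOISE_SD,
                            seed: int = 0,
                            subject_height_cm: float = 166.4,
                            height_sd_cm: float = 0.0) -> pd.DataFrame:
    """Labeled feature table, reproducible under ``seed``.

    Returns a DataFrame with ``subject_id``, ``label`` and the 38 feature
    columns.  ``effects`` maps each label to ``{perturbation: (mean, sd)}``;
    unlisted perturbations are zero.
    """
    n_per_class = dict(DEFAULT_CLASS_COUNTS if n_per_class is None else n_per_class)
    effects = DEFAULT_CLASS_EFFECTS if effects is None else effects

    if any(c < 0 for c in n_per_class.values()):
        raise ValueError("class counts must be non-negative")
    if sum(n_per_class.values()) == 0:
        raise ValueError("at least one subject is required")
    missing = set(n_per_class) - set(effects)
    if missing:
        raise ValueError(f"effects not defined for label(s): {sorted(missing)}")
    for label, eff in effects.items():
        unknown = set(eff) - set(PERTURBATION_NAMES)
        if unknown:
            raise ValueError(
                f"unknown perturbation(s) for {label!r}: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for label in sorted(n_per_class):
        eff = effects[label]
        for _ in range(n_per_class[label]):
            pert = {name: rng.normal(*eff[name]) if name in eff else 0.0
                    for name in PERTURBATION_NAMES}
            h = subject_height_cm + (rng.normal(0.0, height_sd_cm)
                                     if height_sd_cm > 0 else 0.0)
            feats = subject_features(pert, h)
            if noise_sd > 0:
                noise = rng.normal(0.0, noise_sd, len(FEATURE_NAMES))
                feats = {k: feats[k] + n for k, n in zip(FEATURE_NAMES, noise)}
            rows.append({"subject_id": f"S{sid:03d}", "label": label, **feats})
            sid += 1
    return pd.DataFrame(rows, columns=["subject_id", "label", *FEATURE_NAMES])
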