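"""Anatomical sites, photographic views and the feature name inventory.

The marker protocol uses 17 anatomical site names, of which 12 are
bilateral, giving 29 physical markers on the body.  Four views are
photographed: anterior, posterior and the two laterals.  Thirty-eight
features are computed in total, 15 of which occur as left/right pairs.
"""

from __future__ import annotations

ANTERIOR = "anterior"
POSTERIOR = "posterior"
LATERAL_LEFT = "lateral_left"
LATERAL_RIGHT = "lateral_right"
VIEWS = (ANTERIOR, POSTERIOR, LATERAL_LEFT, LATERAL_RIGHT)

# In the anterior view the subject faces the camera, so the subject's right
# side appears on the image's left: the view is mirrored.  Posterior and
# lateral views are not.
VIEW_MIRRORED = {
    ANTERIOR: True,
    POSTERIOR: False,
    LATERAL_LEFT: False,
    LATERAL_RIGHT: False,
}

MIDLINE_SITES = (
    "jugular_notch",
    "xiphoid",
    "C7",
    "kyphosis_apex",
    "lordosis_apex",
)

BILATERAL_SITES = (
    "acromion",
    "ASIS",
    "PSIS",
    "trochanter",
    "femur_lateral_condyle",
    "popliteal_fossa",
    "patella",
    "tibial_tuberosity",
    "lateral_malleolus",
    "posterior_intermalleolar_point",
    "calcaneus",
    "fifth_metatarsal",
)

SITE_NAMES = MIDLINE_SITES + BILATERAL_SITES

#: physical marker count: midline sites once, bilateral sites twice
N_PHYSICAL_MARKERS = len(MIDLINE_SITES) + 2 * len(BILATERAL_SITES)


def site_key(name: str, side: str | None = None) -> str:
    """Canonical key for a site instance, e.g. ``acromion_L`` or ``C7``.

    ``side`` must be ``"L"``/``"R"`` for bilateral sites and ``None`` for
    midline sites.
    """
    if name not in SITE_NAMES:
        raise ValueError(f"unknown anatomical site {name!r}")
    bilateral = name in BILATERAL_SITES
    if bilateral:
        if side not in ("L", "R"):
            raise ValueError(f"site {name!r} is bilateral; side must be L or R")
        return f"{name}_{side}"
    if side is not None:
        raise ValueError(f"site {name!r} is midline; side must be None")
    return name


def split_site_key(key: str) -> tuple[str, str | None]:
    """Inverse of :func:`site_key`."""
    if key.endswith(("_L", "_R")):
        return key[:-2], key[-1]
    return key, None


# Sites each view must provide, driven by the feature definitions below.
VIEW_SITES = {
    ANTERIOR: (
        "jugular_notch", "xiphoid",
        "acromion_L", "acromion_R",
        "ASIS_L", "ASIS_R",
        "trochanter_L", "trochanter_R",
        "patella_L", "patella_R",
        "tibial_tuberosity_L", "tibial_tuberosity_R",
        "lateral_malleolus_L", "lateral_malleolus_R",
    ),
    POSTERIOR: (
        "C7", "kyphosis_apex", "lordosis_apex",
        "acromion_L", "acromion_R",
        "PSIS_L", "PSIS_R",
        "trochanter_L", "trochanter_R",
        "popliteal_fossa_L", "popliteal_fossa_R",
        "posterior_intermalleolar_point_L", "posterior_intermalleolar_point_R",
        "calcaneus_L", "calcaneus_R",
    ),
    LATERAL_LEFT: (
        "C7", "kyphosis_apex", "lordosis_apex",
        "ASIS_L", "PSIS_L", "trochanter_L",
        "femur_lateral_condyle_L", "lateral_malleolus_L",
        "calcaneus_L", "fifth_metatarsal_L",
    ),
    LATERAL_RIGHT: (
        "C7", "kyphosis_apex", "lordosis_apex",
        "ASIS_R", "PSIS_R", "trochanter_R",
        "femur_lateral_condyle_R", "lateral_malleolus_R",
        "calcaneus_R", "fifth_metatarsal_R",
    ),
}

# ---------------------------------------------------------------------------
# Feature inventory (38 names, 15 left/right pairs)

ANTERIOR_FEATURES = (
    "AHA_A", "ASA", "ASISHA",
    "ASISLA_L", "ASISLA_R",
    "AKLA_L", "AKLA_R",
    "AJND_L", "AJND_R",
    "AAD_L", "AAD_R",
    "ALLL_L", "ALLL_R",
)
POSTERIOR_FEATURES = (
    "AHA_P", "AVA", "TKA", "LLA", "PSISHA",
    "PSISLA_L", "PSISLA_R",
    "PKLA_L", "PKLA_R",
    "ALA_L", "ALA_R",
    "APD_L", "APD_R",
    "PLLL_L", "PLLL_R",
)
LATERAL_FEATURES = (
    "TKC_L", "TKC_R",
    "LLC_L", "LLC_R",
    "PLA_L", "PLA_R",
    "KA_L", "KA_R",
    "LFA_L", "LFA_R",
)

FEATURE_NAMES = ANTERIOR_FEATURES + POSTERIOR_FEATURES + LATERAL_FEATURES

#: base names that occur as _L/_R pairs
BILATERAL_FEATURES = tuple(sorted(
    {n[:-2] for n in FEATURE_NAMES if n.endswith("_L")}
))

#: features measured in cm; everything else is an angle in degrees
DISTANCE_FEATURES = (
    "AJND_L", "AJND_R", "AAD_L", "AAD_R", "ALLL_L", "ALLL_R",
    "APD_L", "APD_R", "PLLL_L", "PLLL_R",
)
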