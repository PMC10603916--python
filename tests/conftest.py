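import numpy as np
import pytest

from postura.detection import DEFAULT_COLORS, detect_blobs, threshold_color
from postura.scene import SceneSpec, render_view
from postura.templates import default_template


@pytest.fixture(scope="session")
def neutral_anterior_scene():
    """One rendered neutral anterior view with its ground truth."""
    spec = SceneSpec(template=default_template("anterior"), seed=7,
                     noise_sd=1.0)
    img, gt = render_view(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def four_view_images():
    """Rendered neutral images and ground truths for all four views."""
    out = {}
    for view in ("anterior", "posterior", "lateral_left", "lateral_right"):
        spec = SceneSpec(template=default_template(view), seed=11,
                         noise_sd=1.0)
        out[view] = render_view(spec)
    return out


def detect_markers(img):
    return detect_blobs(threshold_color(img, DEFAULT_COLORS["green"]))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
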