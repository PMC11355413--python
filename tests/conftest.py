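import numpy as np
import pytest

from fibroct.phantom import PhantomSpec, generate_phantom
from fibroct.segmentation import SnakeConfig


@pytest.fixture(scope="session")
def disc_image():
    """256x256 image with a bright disc of radius 60 at the centre."""
    rr, cc = np.mgrid[0:256, 0:256]
    inside = (rr - 128.0) ** 2 + (cc - 128.0) ** 2 <= 60.0 ** 2
    return inside.astype(float) * 1000.0 - 800.0


@pytest.fixture(scope="session")
def phantom_10pct():
    """Noise-free phantom with a 10% planted fibrosis fraction."""
    spec = PhantomSpec(fibrosis_fraction=0.10, seed=7)
    ct, truth = generate_phantom(spec)
    return spec, ct, truth


@pytest.fixture()
def default_snake():
    return SnakeConfig()


def manual_init_config(spec, image_id, margin=1.05):
    """Per-image config placing the initial contour near the true boundary,
    standing in for the manually-tuned initial parameters of the protocol."""
    cr, cc = spec.center
    ar, ac = spec.heart_axes
    return {"images": {image_id: {"center": [cr, cc],
                                  "axes": [ar * margin, ac * margin]}}}
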