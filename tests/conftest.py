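import numpy as np
import pytest

from chartcal.chart import load_reference
from chartcal.synthetic import CameraModel, SceneSpec, render_scene


@pytest.fixture(scope="session")
def chart():
    return load_reference()


@pytest.fixture(scope="session")
def identity_scene(chart):
    """Clean chart scene through an identity (exact-sRGB) camera, noise sd 1."""
    spec = SceneSpec(seed=11)
    cam = CameraModel.identity(noise_sd=1.0)
    img, gt = render_scene(spec, cam, chart)
    return img, gt


@pytest.fixture(scope="session")
def noiseless_scene(chart):
    """Bit-exact chart scene: identity camera, no noise."""
    spec = SceneSpec(seed=12)
    cam = CameraModel.identity(noise_sd=0.0)
    img, gt = render_scene(spec, cam, chart)
    return img, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
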