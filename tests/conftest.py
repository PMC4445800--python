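import numpy as np
import pytest

from leafmotion import BlobSceneSpec
from leafmotion.synth import render_blob_frame


@pytest.fixture
def time_grid_120h() -> np.ndarray:
    """The standard 5-day, 20-minute sampling grid (hours)."""
    return np.arange(361) / 3.0


@pytest.fixture
def blob_scene() -> BlobSceneSpec:
    """A small static blob scene used for frame-pair fixtures."""
    return BlobSceneSpec(
        frame_size=(64, 64), blob_sigma=(8.0, 6.0), oscillation_amplitude=0.0
    )


@pytest.fixture
def blob_pair_factory(blob_scene):
    """Render (reference, shifted) noise-free blob frame pairs."""

    def make(dy: float, dx: float = 0.0):
        cy, cx = blob_scene.center_yx
        f0 = render_blob_frame(blob_scene, cy, cx)
        f1 = render_blob_frame(blob_scene, cy + dy, cx + dx)
        return f0, f1

    return make
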