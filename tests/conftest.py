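import numpy as np
import pytest

from autoprofiler.imaging import DetectionParams
from autoprofiler.synthgen import ScenePreset, generate_scene


@pytest.fixture(scope="session")
def detection_params():
    return DetectionParams()


@pytest.fixture(scope="session")
def small_scene():
    """A 4-cell, 2-frame scene with known ground truth."""
    preset = ScenePreset(n_cells=4, image_shape=(256, 256), ap_rate=3.0, al_rate=3.0, seed=2)
    return generate_scene(preset, 2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
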