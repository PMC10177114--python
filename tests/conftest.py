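import numpy as np
import pytest

from oriface.synth import SyntheticSceneSpec, generate_dataset, generate_scene


@pytest.fixture(scope="session")
def small_scene_spec():
    return SyntheticSceneSpec(size=96, face_radius=(10.0, 18.0), faces_min=1, faces_max=2)


@pytest.fixture(scope="session")
def sample_scenes(small_scene_spec):
    """A small bank of synthetic scenes with exact ground truth."""
    return generate_dataset(12, small_scene_spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
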