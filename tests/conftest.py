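import numpy as np
import pytest

from xleaf import NetworkSpec, SceneConfig, build_dataset


@pytest.fixture(scope="session")
def small_scene_cfg():
    return SceneConfig(image_size=(32, 32))


@pytest.fixture(scope="session")
def small_dataset(small_scene_cfg):
    """20-sample fake-vs-real set at 32x32; shared by training tests."""
    return build_dataset("fake_vs_real", small_scene_cfg, 20,
                         (0.6, 0.2, 0.2), seed=7)


@pytest.fixture(scope="session")
def tiny_spec():
    return NetworkSpec(variant="tiny", n_classes=2, input_size=(32, 32, 3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
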