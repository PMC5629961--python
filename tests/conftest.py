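import numpy as np
import pytest

from glandseg.synthetic import SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benign_scene():
    """Well-separated benign glands: image, labels, separator mask."""
    return generate_scene(SceneConfig(seed=3, n_glands=5, shape=(192, 192)))


@pytest.fixture(scope="session")
def malignant_scene():
    return generate_scene(
        SceneConfig(seed=11, n_glands=5, shape=(192, 192), malignant=True)
    )


@pytest.fixture(scope="session")
def touching_scene():
    """Scene with near-touching gland pairs (separator ground truth present)."""
    return generate_scene(
        SceneConfig(seed=0, n_glands=6, shape=(256, 256),
                    touching_fraction=0.7, touch_gap=3.0)
    )



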