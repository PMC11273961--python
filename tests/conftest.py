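import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def two_mouse_scene():
    from murimetry.synthetic import SceneConfig, generate_scene

    return generate_scene(SceneConfig(n_mice=2, seed=3))


@pytest.fixture(scope="session")
def micro_samples():
    """A handful of small scenes for fast training-loop contract tests."""
    from murimetry.synthetic import SceneConfig, generate_scene
    from murimetry.train import samples_from_scenes

    scenes = [generate_scene(SceneConfig(n_mice=1 + i % 2, seed=100 + i))
              for i in range(6)]
    return samples_from_scenes(scenes)
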