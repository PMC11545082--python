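import numpy as np
import pytest

from cagepose import MergedFrame, SceneConfig, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """One default scene (seed 1): 2 lying, 1 standing, 1 pillar, 1° roll."""
    return generate_scene(SceneConfig(seed=1))


@pytest.fixture(scope="session")
def flat_scene():
    """A roll-free scene for tests that address the unrotated geometry."""
    return generate_scene(SceneConfig(seed=3, roll_angle_deg=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_frame(rng, height=48, width=64):
    """A random but valid merged frame (for format round-trip tests)."""
    color = rng.integers(0, 256, (height, width, 3)).astype(np.uint8)
    depth = rng.integers(0, 65536, (height, width)).astype(np.uint16)
    return MergedFrame(color=color, depth=depth)
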