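import numpy as np
import pytest

from nanospine import SceneConfig, build_scene, render_channels
from nanospine.spines import analyze_spines


@pytest.fixture(scope="session")
def small_scene():
    """A 16-spine scene with its rendered channels, shared across tests."""
    cfg = SceneConfig(n_spines=16, seed=42, exact_fractions=True, p_tc=0.25)
    scene = build_scene(cfg)
    grids = scene.default_grids()
    stacks = render_channels(scene, grids)
    return scene, grids, stacks


@pytest.fixture(scope="session")
def small_scene_analysis(small_scene):
    scene, grids, stacks = small_scene
    result = analyze_spines(stacks, grids, truth=scene)
    return scene, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
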