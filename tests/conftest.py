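import numpy as np
import pytest

from tillersight import RunConfig, SceneParams, generate_scene, render_scene
from tillersight.preprocess import (
    ThresholdConfig,
    binarize_green,
    decorrelation_stretch,
    remove_small_components,
)


@pytest.fixture(scope="session")
def default_cfg() -> RunConfig:
    return RunConfig()


def scene_mask(img: np.ndarray, cfg: RunConfig) -> np.ndarray:
    """The preprocessing front half of the pipeline, as tests need it."""
    stretched = decorrelation_stretch(img)
    mask = binarize_green(stretched, ThresholdConfig(k=cfg.k))
    return remove_small_components(mask, cfg.min_component_area)


@pytest.fixture(scope="session")
def clean_scene():
    """One deterministic clean 8-leaf scene shared across tests."""
    scene = generate_scene(SceneParams(n_long_leaves=8, seed=123))
    return scene, render_scene(scene)
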