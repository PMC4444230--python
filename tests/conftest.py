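import numpy as np
import pytest

from planktosort.config import PipelineConfig
from planktosort.synthscene import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def quarter_config() -> PipelineConfig:
    return PipelineConfig().scaled(0.25)


@pytest.fixture(scope="session")
def small_scene():
    """One quarter-scale scene with a few of every object class."""
    cfg = SceneConfig.quarter(
        n_copepod=2, n_arrow=1, n_gelatinous=1, n_bubble=2, seed=11
    )
    return generate_scene(cfg, image_id="fix_0000")


@pytest.fixture(scope="session")
def sparse_scene():
    """A small, fast scene: 320x320 with a handful of objects."""
    cfg = SceneConfig(
        width=320, height=320, scale=0.25, n_particulates=60,
        n_copepod=2, n_arrow=0, n_gelatinous=0, n_bubble=1, seed=7,
    )
    return generate_scene(cfg, image_id="sparse_0000")


@pytest.fixture(scope="session")
def tiny_library():
    """A small labeled crop library harvested from truth boxes.

    Sized for speed (not the full 80/65/65 study ratios): enough exemplars
    per class to train separable toy models.
    """
    from planktosort.synthscene import (
        SceneConfig, TARGET_CLASSES, generate_benchmark,
    )

    cfg = SceneConfig.quarter(
        n_copepod=3, n_arrow=3, n_gelatinous=3, n_bubble=3,
        n_particulates=200, seed=29,
    )
    bench = generate_benchmark(
        cfg, 1, seed=29, n_train=6,
        level1_sizes={c: 10 for c in TARGET_CLASSES},
        level2_targets=10, level2_nontargets=60,
    )
    return bench.library


@pytest.fixture(scope="session")
def tiny_models(tiny_library, quarter_config):
    from planktosort.benchmark import train_models

    return train_models(tiny_library, quarter_config, seed=5)
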