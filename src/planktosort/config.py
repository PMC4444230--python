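"""Validated pipeline configuration with YAML round-trip.

All stages read their parameters from one :class:`PipelineConfig` so a run's
full parameter ledger can be archived next to its outputs.  Unknown keys are
rejected on load.  Defaults are the operating point for full-scale frames
(2448x2050 at ~10 um/px): 77x77 Sauvola window with k=0.6 and R=128, a
5000 px (~0.5 mm^2) MSER area gate, 16 px HOG cells with 9 orientation bins,
and 250/150 px normalization sides for the two classifier levels.
``scaled()`` derives a config for linearly downscaled frames, shrinking the
window and the area gates proportionally while keeping the normalization
sides (the descriptor layout) fixed.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .roi_features import HogParams
from .segmentation import MserParams, SauvolaParams


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SauvolaConfig(_Model):
    window: int = 77
    k: float = 0.6
    R: float = 128.0

    def to_params(self) -> SauvolaParams:
        return SauvolaParams(window=self.window, k=self.k, R=self.R)


class MserConfig(_Model):
    delta: int = 2
    max_variation: float = 0.5
    min_area: int = 5000
    max_area: int | None = None

    def to_params(self) -> MserParams:
        return MserParams(delta=self.delta, max_variation=self.max_variation,
                          min_area=self.min_area, max_area=self.max_area)


class SegmentationConfig(_Model):
    sauvola: SauvolaConfig = SauvolaConfig()
    mser: MserConfig = MserConfig()
    min_roi_area: int = 50
    dedup_threshold: float = 0.8


class HogConfig(_Model):
    cell: int = 16
    bins: int = 9
    block: int = 2
    block_stride: int = 1
    clip: float = 0.2

    def to_params(self) -> HogParams:
        return HogParams(cell=self.cell, bins=self.bins, block=self.block,
                         block_stride=self.block_stride, clip=self.clip)


class FeatureConfig(_Model):
    hog: HogConfig = HogConfig()
    level1_side: int = 250
    level2_side: int = 150
    stretch: bool = False


class ClassifierConfig(_Model):
    C: float = 1.0
    seed: int = 0
    weight_cap: float = 10.0


class EvaluationConfig(_Model):
    mode: str = "iou"
    iou_threshold: float = 0.3


class PipelineConfig(_Model):
    segmentation: SegmentationConfig = SegmentationConfig()
    features: FeatureConfig = FeatureConfig()
    classifier: ClassifierConfig = ClassifierConfig()
    evaluation: EvaluationConfig = EvaluationConfig()
    pixel_size_um: float = 10.0

    def scaled(self, factor: float) -> "PipelineConfig":
        """Config for frames downscaled by ``factor`` linearly."""
        if not 0 < factor <= 1:
            raise ValueError("factor must be in (0, 1]")
        cfg = self.model_copy(deep=True)
        win = max(3, int(round(self.segmentation.sauvola.window * factor)))
        cfg.segmentation.sauvola.window = win + 1 if win % 2 == 0 else win
        cfg.segmentation.mser.min_area = max(
            1, int(round(self.segmentation.mser.min_area * factor * factor))
        )
        cfg.segmentation.min_roi_area = max(
            1, int(round(self.segmentation.min_roi_area * factor * factor))
        )
        cfg.pixel_size_um = self.pixel_size_um / factor
        return cfg


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)


def convert_area(pixels: float, pixel_size_um: float = 10.0) -> float:
    """Pixel count to mm^2 at the given pixel pitch."""
    if pixels < 0:
        raise ValueError("pixels must be >= 0")
    return pixels * (pixel_size_um / 1000.0) ** 2
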