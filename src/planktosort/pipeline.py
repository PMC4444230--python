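"""End-to-end orchestration: segment every frame, classify every ROI.

`run_pipeline` is deterministic given (config, models): frames are processed
in sorted image-id order, per-image failures are logged and skipped rather
than aborting the batch, and the detection table is sorted by
(image_id, roi_id) so output is independent of directory listing order.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import Detection, LinearModel, classify_roi
from .config import PipelineConfig, dump_config
from .segmentation import (
    ROI,
    combine_masks,
    deduplicate_rois,
    extract_rois,
    mser_large,
    sauvola_mask,
)
from .synthscene import Scene

logger = logging.getLogger("planktosort")

IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".bmp")


def segment_image(image: np.ndarray, config: PipelineConfig) -> list[ROI]:
    """Sauvola + MSER masks, union, connected components, dedup."""
    seg = config.segmentation
    small = sauvola_mask(image, seg.sauvola.to_params())
    large = mser_large(image, seg.mser.to_params())
    mask = combine_masks(small, large)
    rois = extract_rois(mask, image, seg.min_roi_area)
    return deduplicate_rois(rois, seg.dedup_threshold)


def classify_image(
    image: np.ndarray,
    image_id: str,
    config: PipelineConfig,
    level1_models: dict[str, LinearModel],
    level2_models: dict[str, LinearModel],
    rois: list[ROI] | None = None,
) -> list[tuple[ROI, Detection]]:
    if rois is None:
        rois = segment_image(image, config)
    feats = config.features
    out = []
    for roi in rois:
        det = classify_roi(
            roi, level1_models, level2_models, feats.hog.to_params(),
            image_id=image_id,
            level1_side=feats.level1_side,
            level2_side=feats.level2_side,
            stretch=feats.stretch,
        )
        out.append((roi, det))
    return out


def make_detector(
    config: PipelineConfig,
    level1_models: dict[str, LinearModel],
    level2_models: dict[str, LinearModel],
):
    """Scene -> [(roi, detection), ...]; the plug-in for hard-negative mining."""

    def detector(scene: Scene):
        return classify_image(
            scene.image, scene.image_id, config, level1_models, level2_models
        )

    return detector


def detections_to_dataframe(detections: Sequence[Detection]) -> pd.DataFrame:
    rows = []
    for d in sorted(detections, key=lambda d: (d.image_id, d.roi_id)):
        m2 = max(d.margins2.values()) if d.margins2 else np.nan
        rows.append(dict(
            image_id=d.image_id, roi_id=d.roi_id, **{"class": d.label},
            top=d.top, left=d.left, height=d.height, width=d.width,
            margin=m2 if d.label != "none" else np.nan,
            review=int(d.review),
        ))
    cols = ["image_id", "roi_id", "class", "top", "left", "height", "width",
            "margin", "review"]
    return pd.DataFrame(rows, columns=cols)


def _load_images(input_dir: Path) -> list[tuple[str, np.ndarray]]:
    import imageio.v3 as iio

    images = []
    for path in sorted(input_dir.iterdir()):
        if path.suffix.lower() not in IMAGE_SUFFIXES:
            continue
        try:
            img = np.asarray(iio.imread(path))
        except Exception as exc:
            logger.warning("skipping unreadable image %s: %s", path.name, exc)
            continue
        if img.ndim == 3:
            img = img[..., 0]
        images.append((path.stem, img.astype(np.uint8)))
    return images


def run_pipeline(
    inputs: str | Path | Sequence[Scene],
    config: PipelineConfig,
    level1_models: dict[str, LinearModel],
    level2_models: dict[str, LinearModel],
    out_dir: str | Path | None = None,
) -> tuple[list[Detection], list[tuple[ROI, Detection]]]:
    """Process a directory of frames (or in-memory scenes).

    Returns (all detections, [(roi, detection)] pairs for every candidate).
    With ``out_dir`` set, writes detections.csv and a copy of the config for
    provenance.
    """
    if isinstance(inputs, (str, Path)):
        frames = _load_images(Path(inputs))
    else:
        frames = [(sc.image_id, sc.image) for sc in inputs]
    if not frames:
        raise ValueError("no readable input images")
    frames.sort(key=lambda f: f[0])

    pairs: list[tuple[ROI, Detection]] = []
    for image_id, image in frames:
        try:
            res = classify_image(image, image_id, config, level1_models, level2_models)
        except Exception as exc:
            logger.warning("skipping image %s: %s", image_id, exc)
            continue
        n_targets = sum(det.label != "none" for _, det in res)
        logger.info("%s: %d candidate objects, %d accepted",
                    image_id, len(res), n_targets)
        pairs.extend(res)

    detections = sorted((d for _, d in pairs), key=lambda d: (d.image_id, d.roi_id))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        detections_to_dataframe(detections).to_csv(out / "detections.csv", index=False)
        dump_config(config, out / "config.yaml")
    return detections, pairs
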