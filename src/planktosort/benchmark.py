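"""Desk-scale synthetic benchmark of the full two-level pipeline.

Generates quarter-scale (612x512) shadowgraph scenes with hundreds of
particulates per frame and targets below 5% of objects, builds a training
library at the study's class-imbalance ratios (level-1 exemplars 80/65/65,
level-2 65 targets vs 985 non-targets per group), trains both classifier
levels, runs one hard-negative-mining round over the training scenes, and
scores the pipeline on held-out scenes with exact synthetic denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classifier import TrainingLibrary, train_level1, train_level2
from .config import PipelineConfig
from .evaluation import (
    MatchCriterion,
    Metrics,
    compute_metrics,
    count_nontarget_candidates,
    match_detections,
)
from .pipeline import make_detector, run_pipeline
from .synthscene import TARGET_CLASSES, SceneConfig, generate_benchmark, generate_scene


@dataclass
class BenchmarkResult:
    metrics: Metrics
    n_test_scenes: int
    n_candidates: int
    n_nontarget_candidates: int
    mined: dict[str, int]
    shifts: tuple[float, float] = (0.0, 0.0)

    def summary(self) -> dict[str, float]:
        per = self.metrics.per_class
        return dict(
            min_tpr=min(per[c]["tpr"] for c in TARGET_CLASSES),
            max_fpr=max(per[c]["fpr"] for c in TARGET_CLASSES),
            min_precision=min(per[c]["precision"] for c in TARGET_CLASSES),
        )


def train_models(
    library: TrainingLibrary,
    config: PipelineConfig,
    seed: int,
    *,
    augment_negatives: bool = False,
    cache=None,
):
    hog = config.features.hog.to_params()
    level1 = train_level1(
        library, hog, seed=seed,
        side=config.features.level1_side, C=config.classifier.C,
        cache=cache,
    )
    level2 = {
        g: train_level2(
            g, library, hog, seed=seed,
            side=config.features.level2_side, C=config.classifier.C,
            weight_cap=config.classifier.weight_cap,
            augment_negatives=augment_negatives, cache=cache,
        )
        for g in sorted(library.level2)
    }
    return level1, level2


def _full_margin_records(scenes, config: PipelineConfig, level1, level2):
    """Segment and describe every candidate once, keeping margins for all
    groups at both levels so operating points can be swept cheaply."""
    from .roi_features import denoise_roi, hog_descriptor, normalize_roi
    from .pipeline import segment_image

    hp = config.features.hog.to_params()
    records = []
    for sc in scenes:
        for roi in segment_image(sc.image, config):
            den = denoise_roi(roi.crop)
            d1 = hog_descriptor(
                normalize_roi(den.gray, config.features.level1_side), hp
            ).values
            d2 = hog_descriptor(
                normalize_roi(den.gray, config.features.level2_side), hp
            ).values
            m1 = {c: m.margin(d1) for c, m in level1.items()}
            m2 = {c: m.margin(d2) for c, m in level2.items()}
            records.append((sc.image_id, roi.id, roi.bbox, m1, m2))
    return records


def _detections_at(records, shift1: float, shift2: float):
    from .classifier import Detection, candidate_classes

    dets = []
    for image_id, roi_id, bbox, m1, m2 in records:
        shifted1 = {c: v + shift1 for c, v in m1.items()}
        cands = candidate_classes(shifted1)
        accepted = {c: m2[c] + shift2 for c in cands if m2[c] + shift2 > 0}
        label = max(sorted(accepted), key=lambda c: accepted[c]) if accepted else "none"
        dets.append(Detection(image_id, roi_id, *bbox, label, shifted1,
                              {c: m2[c] + shift2 for c in cands}))
    return dets


#: calibration selection rule: among shift pairs meeting these floors on the
#: annotated validation scenes, maximize the minimum per-class TPR (ties to
#: the smallest shifts).  Floors sit one standard error above the 80%/10%
#: operating-point requirements: per-class precision on ~75 accepted
#: validation detections carries an s.e. of ~0.04, FPR (denominator in the
#: thousands) far less.
CALIBRATION_PRECISION_FLOOR = 0.84
CALIBRATION_FPR_CEILING = 0.08
CALIBRATION_GRID1 = (0.0, 0.3, 0.6, 0.9)
CALIBRATION_GRID2 = (0.0, 0.2, 0.4)


def calibrate_operating_point(
    scenes, config: PipelineConfig, level1, level2
) -> tuple[float, float]:
    """Pick bias shifts for both levels on annotated validation scenes.

    The raw SVM biases sit at the hard-margin midpoint of a separable
    training set, which is conservative on fresh data; the operational
    choice — how much routing and acceptance slack to allow — is made the
    way the original procedure controlled its false-positive rate and
    accuracy: by scoring candidate operating points on held-out annotated
    frames.  The chosen shifts are folded into the model biases, so the
    accept rule everywhere stays "margin > 0".
    """
    records = _full_margin_records(scenes, config, level1, level2)
    truths = [t for sc in scenes for t in sc.truth]
    criterion = MatchCriterion(
        mode=config.evaluation.mode, iou_threshold=config.evaluation.iou_threshold
    )
    best = (0.0, 0.0)
    best_score = -1.0
    for s1 in CALIBRATION_GRID1:
        for s2 in CALIBRATION_GRID2:
            dets = _detections_at(records, s1, s2)
            accepted = [d for d in dets if d.label != "none"]
            match = match_detections(accepted, truths, criterion)
            n_non = count_nontarget_candidates(dets, truths, criterion)
            met = compute_metrics(match, n_nontarget_candidates=n_non)
            per = met.per_class
            vals = [per[c] for c in TARGET_CLASSES]
            if any(v["precision"] is None or v["tpr"] is None for v in vals):
                continue
            if min(v["precision"] for v in vals) < CALIBRATION_PRECISION_FLOOR:
                continue
            if max(v["fpr"] for v in vals) > CALIBRATION_FPR_CEILING:
                continue
            score = min(v["tpr"] for v in vals)
            if score > best_score + 1e-12:
                best_score = score
                best = (s1, s2)
    return best


def run_benchmark(
    seed: int = 0,
    n_test_scenes: int = 200,
    n_train_scenes: int = 45,
    *,
    mining_rounds: int = 2,
    n_mining_scenes: int = 100,
    n_calibration_scenes: int = 30,
    scene_config: SceneConfig | None = None,
    config: PipelineConfig | None = None,
) -> BenchmarkResult:
    """Train, mine, calibrate, classify held-out scenes, and score per class.

    Hard negatives are mined from ``n_mining_scenes`` dedicated survey-mix
    scenes (disjoint seeds from both library and test scenes) plus the
    library scenes — the analog of running the freshly trained pipeline over
    a batch of random survey frames and filing its false positives.  The
    operating point (bias shifts at both levels) is then calibrated on
    ``n_calibration_scenes`` further annotated scenes, disjoint from
    everything else.
    """
    seed = int(seed) % (2**31 - 1)
    if scene_config is None:
        scene_config = SceneConfig.quarter(
            n_copepod=2, n_arrow=1, n_gelatinous=1, n_bubble=2, seed=seed
        )
    if config is None:
        config = PipelineConfig().scaled(0.25)

    from .pipeline import segment_image

    bench = generate_benchmark(
        scene_config, n_test_scenes, seed, n_train=n_train_scenes,
        segmenter=lambda image: segment_image(image, config),
        match_iou=config.evaluation.iou_threshold,
    )
    from .classifier import DescriptorCache

    cache = DescriptorCache()
    library = bench.library
    level1, level2 = train_models(
        library, config, seed, augment_negatives=True, cache=cache
    )

    from dataclasses import replace as _replace

    mining_scenes = bench.train_scenes + [
        generate_scene(
            _replace(scene_config, seed=seed + 500_000 + i),
            image_id=f"mine_{i:04d}",
        )
        for i in range(n_mining_scenes)
    ]
    mined_total = {g: 0 for g in library.level2}
    for r in range(mining_rounds):
        from .classifier import hard_negative_mine

        detector = make_detector(config, level1, level2)
        library, added = hard_negative_mine(
            mining_scenes, detector, library,
            n_images=len(mining_scenes), seed=seed + 7000 + r,
            iou_threshold=config.evaluation.iou_threshold,
        )
        for g, n in added.items():
            mined_total[g] += n
        if sum(added.values()) == 0:
            break
        hog = config.features.hog.to_params()
        level2 = {
            g: train_level2(
                g, library, hog, seed=seed,
                side=config.features.level2_side, C=config.classifier.C,
                weight_cap=config.classifier.weight_cap,
                augment_negatives=True, cache=cache,
            )
            for g in sorted(library.level2)
        }

    shift1, shift2 = 0.0, 0.0
    if n_calibration_scenes > 0:
        calib_scenes = [
            generate_scene(
                _replace(scene_config, seed=seed + 700_000 + i),
                image_id=f"calib_{i:04d}",
            )
            for i in range(n_calibration_scenes)
        ]
        shift1, shift2 = calibrate_operating_point(
            calib_scenes, config, level1, level2
        )
        for m in level1.values():
            m.b += shift1
        for m in level2.values():
            m.b += shift2

    detections, pairs = run_pipeline(bench.test_scenes, config, level1, level2)
    truths = [t for sc in bench.test_scenes for t in sc.truth]
    criterion = MatchCriterion(
        mode=config.evaluation.mode, iou_threshold=config.evaluation.iou_threshold
    )
    accepted = [d for d in detections if d.label != "none"]
    match = match_detections(accepted, truths, criterion)
    n_non = count_nontarget_candidates(detections, truths, criterion)
    metrics = compute_metrics(match, n_nontarget_candidates=n_non)
    return BenchmarkResult(
        metrics=metrics,
        n_test_scenes=n_test_scenes,
        n_candidates=len(detections),
        n_nontarget_candidates=n_non,
        mined=mined_total,
        shifts=(shift1, shift2),
    )
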