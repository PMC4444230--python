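"""Two-level hierarchical linear-SVM classification of segmented ROIs.

Every candidate ROI — target or not — is first routed by three one-vs-rest
linear classifiers (arrow / copepod / gelatinous, trained on target exemplars
at a 250 px normalization) to the shape groups it resembles: all groups with
a positive margin, or the single greatest-margin group if none is positive.
Each candidate group then applies its own binary classifier (trained at a
150 px normalization on targets vs a large non-target set) and accepts only
positive margins; with several acceptances the greatest level-2 margin wins;
with none the ROI is discarded as a non-target.  The split matters because
non-targets outnumber targets by >20:1 and many mimic one specific group
(bubbles vs gelatinous bells, elongated detritus vs arrow worms): the second
level can learn exactly that confusion.

Group libraries are grown by hard-negative mining, the same reiterative
process used to build them by hand: run the full pipeline, harvest accepted
detections that do not match ground truth, add them as non-targets, retrain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .roi_features import HogParams, denoise_roi, hog_descriptor, normalize_roi

TARGET_CLASSES = ("arrow", "copepod", "gelatinous")

LEVEL1_SIDE = 250
LEVEL2_SIDE = 150


@dataclass
class LinearModel:
    """f(X) = W·X + b; positive margin means membership in `label`."""

    w: np.ndarray
    b: float
    label: str
    meta: dict = field(default_factory=dict)

    def margin(self, x: np.ndarray) -> float:
        return float(self.w @ x + self.b)


@dataclass
class TrainingLibrary:
    """Labeled crop sets: level-1 target exemplars per class; level-2 target
    and non-target crops per group."""

    level1: dict[str, list[np.ndarray]]
    level2: dict[str, tuple[list[np.ndarray], list[np.ndarray]]]

    def validate(self) -> None:
        for cls, crops in self.level1.items():
            if not crops:
                raise ValueError(f"level-1 class {cls!r} is empty")
        for grp, (pos, neg) in self.level2.items():
            if not pos or not neg:
                raise ValueError(f"level-2 group {grp!r} needs both target and non-target crops")


@dataclass
class Detection:
    image_id: str
    roi_id: int
    top: int
    left: int
    height: int
    width: int
    label: str  # one of TARGET_CLASSES or "none"
    margins1: dict[str, float]
    margins2: dict[str, float]
    review: bool = False
    error: str | None = None

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        return (self.top, self.left, self.height, self.width)


def _dihedral(crop: np.ndarray) -> list[np.ndarray]:
    """The 8 axis-aligned flips/rotations of a crop.

    Organisms appear at arbitrary orientations while exemplar libraries are
    small; symmetrizing the library is cheaper than demanding the library
    cover every pose."""
    r1 = np.rot90(crop)
    r2 = np.rot90(crop, 2)
    r3 = np.rot90(crop, 3)
    return [crop, np.fliplr(crop), np.flipud(crop), crop.T,
            r1, r2, r3, np.fliplr(r1)]


def crop_descriptor(
    crop: np.ndarray,
    side: int,
    hog_params: HogParams | None = None,
    *,
    stretch: bool = False,
) -> np.ndarray:
    """denoise -> normalize to `side` -> HOG, the shared feature pipeline."""
    den = denoise_roi(crop)
    norm = normalize_roi(den.gray, side, stretch=stretch)
    return hog_descriptor(norm, hog_params or HogParams()).values


class DescriptorCache(dict):
    """Memo for library-crop descriptors across training rounds.

    Keys on (id(crop), variant, side), so callers must keep the crop arrays
    alive for the cache's lifetime (a training library does).  Mining rounds
    retrain level 2 repeatedly on a mostly unchanged library; without the
    cache every round recomputes thousands of identical descriptors.
    """

    def descriptor(self, crop, variant: int, side: int, hog_params) -> np.ndarray:
        key = (id(crop), variant, side)
        if key not in self:
            var = _dihedral(crop)[variant] if variant else crop
            self[key] = crop_descriptor(var, side, hog_params)
        return self[key]


def _fit_binary(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    seed: int,
    class_weight: dict | None = None,
    max_iter: int = 20000,
) -> tuple[np.ndarray, float]:
    svm = LinearSVC(
        C=C,
        loss="hinge",
        dual=True,
        tol=1e-5,
        max_iter=max_iter,
        random_state=seed,
        class_weight=class_weight,
    )
    svm.fit(X, y)
    # sklearn orders classes_ ascending; ensure margin > 0 means y == 1
    assert list(svm.classes_) == [0, 1]
    return svm.coef_[0].copy(), float(svm.intercept_[0])


def train_level1(
    library: TrainingLibrary,
    hog_params: HogParams | None = None,
    seed: int = 0,
    *,
    side: int = LEVEL1_SIDE,
    C: float = 1.0,
    augment: bool = True,
    cache: DescriptorCache | None = None,
) -> dict[str, LinearModel]:
    """One-vs-rest linear SVMs over HOG descriptors of the target exemplars.

    With ``augment`` (default) every exemplar also contributes its 8
    flip/rotation variants, widening the pose coverage of a small library.
    """
    library.validate()
    hog_params = hog_params or HogParams()
    cache = cache if cache is not None else DescriptorCache()
    classes = sorted(library.level1)
    feats, labels = [], []
    for cls in classes:
        for crop in library.level1[cls]:
            for v in (range(8) if augment else range(1)):
                feats.append(cache.descriptor(crop, v, side, hog_params))
                labels.append(cls)
    X = np.vstack(feats)
    labels = np.array(labels)
    models: dict[str, LinearModel] = {}
    for cls in classes:
        y = (labels == cls).astype(int)
        # one class vs the union of the rest is ~1:2 imbalanced; balance so
        # a routing margin near zero is not systematically pushed negative
        cw = {1: (len(y) - y.sum()) / y.sum(), 0: 1.0}
        w, b = _fit_binary(X, y, C, seed, class_weight=cw)
        models[cls] = LinearModel(
            w=w, b=b, label=cls,
            meta=dict(level=1, side=side, n_pos=int(y.sum()), n=len(y), seed=seed, C=C),
        )
    return models


def train_level2(
    group: str,
    library: TrainingLibrary,
    hog_params: HogParams | None = None,
    seed: int = 0,
    *,
    side: int = LEVEL2_SIDE,
    C: float = 1.0,
    weight_cap: float = 10.0,
    augment: bool = True,
    augment_negatives: bool = False,
    cache: DescriptorCache | None = None,
) -> LinearModel:
    """Group-specific binary SVM: target (y=1) vs non-target (y=0) crops.

    The non-target majority is counterbalanced by an inverse-frequency
    positive-class weight, capped at ``weight_cap`` so a 985:65 library does
    not swamp the margin entirely.  ``augment`` adds the 8 flip/rotation
    variants of every target crop; ``augment_negatives`` does the same for
    non-targets, widening coverage of the detritus pose space.
    """
    if group not in library.level2:
        raise ValueError(f"no level-2 library for group {group!r}")
    pos, neg = library.level2[group]
    if not pos or not neg:
        raise ValueError(f"level-2 group {group!r} needs both target and non-target crops")
    hog_params = hog_params or HogParams()
    cache = cache if cache is not None else DescriptorCache()
    n_pv = 8 if augment else 1
    n_nv = 8 if augment_negatives else 1
    feats = [cache.descriptor(c, v, side, hog_params) for c in pos for v in range(n_pv)]
    n_pos = len(feats)
    feats += [cache.descriptor(c, v, side, hog_params) for c in neg for v in range(n_nv)]
    X = np.vstack(feats)
    y = np.array([1] * n_pos + [0] * (len(feats) - n_pos))
    cw = {1: min((len(feats) - n_pos) / n_pos, weight_cap), 0: 1.0}
    w, b = _fit_binary(X, y, C, seed, class_weight=cw)
    return LinearModel(
        w=w, b=b, label=group,
        meta=dict(level=2, side=side, n_pos=len(pos), n_neg=len(neg),
                  seed=seed, C=C, weight_cap=weight_cap),
    )


def candidate_classes(margins: dict[str, float]) -> list[str]:
    """Level-1 routing rule: every positive-margin class, else the argmax.

    Never empty — a candidate with no resemblance anywhere is still routed to
    its least-unlike group and left for level 2 to reject.
    """
    pos = [c for c, m in margins.items() if m > 0]
    if pos:
        return sorted(pos)
    return [max(sorted(margins), key=lambda c: margins[c])]


def predict_level1(
    descriptor: np.ndarray, models: dict[str, LinearModel]
) -> tuple[list[str], dict[str, float]]:
    margins = {cls: m.margin(descriptor) for cls, m in sorted(models.items())}
    return candidate_classes(margins), margins


def classify_roi(
    roi,
    level1_models: dict[str, LinearModel],
    level2_models: dict[str, LinearModel],
    hog_params: HogParams | None = None,
    *,
    image_id: str = "",
    level1_side: int = LEVEL1_SIDE,
    level2_side: int = LEVEL2_SIDE,
    stretch: bool = False,
) -> Detection:
    """Run one ROI through both levels; failures yield an error Detection."""
    hog_params = hog_params or HogParams()
    try:
        den = denoise_roi(roi.crop)
        d1 = hog_descriptor(
            normalize_roi(den.gray, level1_side, stretch=stretch), hog_params
        ).values
        candidates, margins1 = predict_level1(d1, level1_models)
        d2 = hog_descriptor(
            normalize_roi(den.gray, level2_side, stretch=stretch), hog_params
        ).values
        margins2 = {g: level2_models[g].margin(d2) for g in candidates}
        accepted = {g: m for g, m in margins2.items() if m > 0}
        if accepted:
            label = max(sorted(accepted), key=lambda g: accepted[g])
        else:
            label = "none"
        return Detection(
            image_id=image_id, roi_id=roi.id,
            top=roi.top, left=roi.left, height=roi.height, width=roi.width,
            label=label, margins1=margins1, margins2=margins2,
        )
    except Exception as exc:  # per-ROI isolation: one bad crop must not abort a batch
        return Detection(
            image_id=image_id, roi_id=roi.id,
            top=roi.top, left=roi.left, height=roi.height, width=roi.width,
            label="none", margins1={}, margins2={}, review=True, error=str(exc),
        )


def _bbox_iou(a, b) -> float:
    top = max(a[0], b[0])
    left = max(a[1], b[1])
    bottom = min(a[0] + a[2], b[0] + b[2])
    right = min(a[1] + a[3], b[1] + b[3])
    if bottom <= top or right <= left:
        return 0.0
    inter = (bottom - top) * (right - left)
    return inter / (a[2] * a[3] + b[2] * b[3] - inter)


def hard_negative_mine(
    scenes: Sequence,
    detector: Callable,
    library: TrainingLibrary,
    n_images: int,
    seed: int = 0,
    *,
    iou_threshold: float = 0.3,
) -> tuple[TrainingLibrary, dict[str, int]]:
    """One mining round: false positives become non-target library crops.

    ``detector(scene)`` must return ``[(roi, detection), ...]`` for every
    candidate ROI of the scene (the full segmentation + classification
    pipeline).  An accepted detection counts as a false positive when no
    ground-truth object of its class reaches ``iou_threshold`` bbox IoU.
    A false positive that still overlaps an organism of its *own* class (a
    fragment, a merged pair, a duplicate box) is skipped — a reviewer would
    never file a crop that does show a copepod as a copepod non-target.  A
    crop showing an organism of a different class, however, genuinely "does
    not contain" the group's taxon and is harvested.  Sampling of the
    ``n_images`` scenes
    is deterministic in ``seed``; a round with zero false positives returns
    the library unchanged.
    """
    rng = np.random.default_rng(seed)
    n = min(n_images, len(scenes))
    idx = sorted(rng.choice(len(scenes), size=n, replace=False).tolist())
    new_level2 = {g: (list(p), list(ng)) for g, (p, ng) in library.level2.items()}
    added = {g: 0 for g in new_level2}
    for i in idx:
        scene = scenes[i]
        for roi, det in detector(scene):
            if det.label == "none" or det.label not in new_level2:
                continue
            matched = any(
                t.cls == det.label and _bbox_iou(det.bbox, t.bbox) >= iou_threshold
                for t in scene.truth
            )
            touches_own = any(
                t.cls == det.label and _bbox_iou(det.bbox, t.bbox) > 0.05
                for t in scene.truth
            )
            if not matched and not touches_own:
                new_level2[det.label][1].append(roi.crop.copy())
                added[det.label] += 1
    out = TrainingLibrary(
        level1={c: list(v) for c, v in library.level1.items()},
        level2=new_level2,
    )
    return out, added
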