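"""Scoring detections against ground truth.

Detections are matched one-to-one to truth objects of the same class by
greedy descending overlap (bbox IoU by default, or a centroid-in-bbox mode
closer to how a human checks a frame).  From the matching come the three
validation quantities:

* true-positive rate  TPR = TP / (TP + FN) per class,
* precision           = TP / (TP + FP) per class,
* false-positive rate = accepted non-truth candidates / all non-truth
  candidate ROIs evaluated.

The FPR denominator is only countable when every candidate ROI is tracked;
with synthetic truth it is exact, which is precisely why the benchmark can
state an operating point.  Divide-by-zero rates are reported as None
(undefined), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classifier import Detection
from .synthscene import TARGET_CLASSES, ObjectTruth


@dataclass(frozen=True)
class MatchCriterion:
    mode: str = "iou"  # "iou" or "centroid"
    iou_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in ("iou", "centroid"):
            raise ValueError("mode must be 'iou' or 'centroid'")
        if not 0 < self.iou_threshold <= 1:
            raise ValueError("iou_threshold must be in (0, 1]")


def bbox_iou(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> float:
    top = max(a[0], b[0])
    left = max(a[1], b[1])
    bottom = min(a[0] + a[2], b[0] + b[2])
    right = min(a[1] + a[3], b[1] + b[3])
    if bottom <= top or right <= left:
        return 0.0
    inter = (bottom - top) * (right - left)
    return inter / (a[2] * a[3] + b[2] * b[3] - inter)


def _overlap_score(det: Detection, truth: ObjectTruth, criterion: MatchCriterion) -> float:
    """Positive score iff the pair is matchable under the criterion."""
    if criterion.mode == "iou":
        iou = bbox_iou(det.bbox, truth.bbox)
        return iou if iou >= criterion.iou_threshold else 0.0
    # centroid mode: truth centroid inside detection bbox; closer is better
    if (det.top <= truth.row < det.top + det.height
            and det.left <= truth.col < det.left + det.width):
        cr = det.top + det.height / 2
        cc = det.left + det.width / 2
        return 1.0 / (1.0 + float(np.hypot(cr - truth.row, cc - truth.col)))
    return 0.0


@dataclass
class MatchResult:
    pairs: dict[str, list[tuple[Detection, ObjectTruth]]]
    false_positives: dict[str, list[Detection]]
    false_negatives: dict[str, list[ObjectTruth]]
    criterion: MatchCriterion


def match_detections(
    detections: Sequence[Detection],
    truths: Sequence[ObjectTruth],
    criterion: MatchCriterion | None = None,
) -> MatchResult:
    """Greedy one-to-one matching by descending overlap, per image and class."""
    criterion = criterion or MatchCriterion()
    classes = sorted(
        {t.cls for t in truths if t.cls in TARGET_CLASSES}
        | {d.label for d in detections if d.label in TARGET_CLASSES}
        | set(TARGET_CLASSES)
    )
    pairs = {c: [] for c in classes}
    fps = {c: [] for c in classes}
    fns = {c: [] for c in classes}
    images = sorted(
        {d.image_id for d in detections} | {t.image_id for t in truths}
    )
    for img in images:
        for cls in classes:
            dets = [d for d in detections if d.image_id == img and d.label == cls]
            trus = [t for t in truths if t.image_id == img and t.cls == cls]
            scored = []
            for di, d in enumerate(dets):
                for ti, t in enumerate(trus):
                    s = _overlap_score(d, t, criterion)
                    if s > 0:
                        scored.append((s, di, ti))
            scored.sort(key=lambda x: (-x[0], x[1], x[2]))
            used_d: set[int] = set()
            used_t: set[int] = set()
            for s, di, ti in scored:
                if di in used_d or ti in used_t:
                    continue
                used_d.add(di)
                used_t.add(ti)
                pairs[cls].append((dets[di], trus[ti]))
            fps[cls].extend(d for di, d in enumerate(dets) if di not in used_d)
            fns[cls].extend(t for ti, t in enumerate(trus) if ti not in used_t)
    return MatchResult(pairs=pairs, false_positives=fps, false_negatives=fns,
                       criterion=criterion)


def count_nontarget_candidates(
    all_detections: Sequence[Detection],
    truths: Sequence[ObjectTruth],
    criterion: MatchCriterion | None = None,
) -> int:
    """Candidate ROIs (accepted or not) that do not cover any truth target —
    the exact FPR denominator available on synthetic data."""
    criterion = criterion or MatchCriterion()
    targets_by_img: dict[str, list[ObjectTruth]] = {}
    for t in truths:
        if t.cls in TARGET_CLASSES:
            targets_by_img.setdefault(t.image_id, []).append(t)
    n = 0
    for d in all_detections:
        trus = targets_by_img.get(d.image_id, [])
        if not any(_overlap_score(d, t, criterion) > 0 for t in trus):
            n += 1
    return n


@dataclass
class Metrics:
    per_class: dict[str, dict]
    micro: dict
    n_nontarget_candidates: int | None = None

    def tpr(self, cls: str) -> float | None:
        return self.per_class[cls]["tpr"]

    def precision(self, cls: str) -> float | None:
        return self.per_class[cls]["precision"]

    def fpr(self, cls: str) -> float | None:
        return self.per_class[cls]["fpr"]


def compute_metrics(
    match: MatchResult, n_nontarget_candidates: int | None = None
) -> Metrics:
    per_class = {}
    tot_tp = tot_fp = tot_fn = 0
    for cls in match.pairs:
        tp = len(match.pairs[cls])
        fp = len(match.false_positives[cls])
        fn = len(match.false_negatives[cls])
        tot_tp += tp
        tot_fp += fp
        tot_fn += fn
        per_class[cls] = dict(
            tp=tp, fp=fp, fn=fn,
            tpr=tp / (tp + fn) if tp + fn else None,
            precision=tp / (tp + fp) if tp + fp else None,
            fpr=(fp / n_nontarget_candidates
                 if n_nontarget_candidates else None),
        )
    micro = dict(
        tp=tot_tp, fp=tot_fp, fn=tot_fn,
        tpr=tot_tp / (tot_tp + tot_fn) if tot_tp + tot_fn else None,
        precision=tot_tp / (tot_tp + tot_fp) if tot_tp + tot_fp else None,
        fpr=(tot_fp / n_nontarget_candidates
             if n_nontarget_candidates else None),
    )
    return Metrics(per_class=per_class, micro=micro,
                   n_nontarget_candidates=n_nontarget_candidates)


def detected_to_visual_ratio(detected: int, visual: int) -> float:
    """Automated count as a fraction of the visual (manual) count."""
    if visual <= 0:
        raise ValueError("visual count must be positive")
    return detected / visual


def summarize_counts(records: Iterable, n_images: int) -> pd.DataFrame:
    """Per-class organism totals, encounter images and encounter fractions.

    ``records`` may be Detections or ObjectTruths (anything with image_id and
    a class label); rows only for target classes present plus all targets.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rows = []
    recs = list(records)
    classes = sorted(
        {getattr(r, "cls", getattr(r, "label", None)) for r in recs} | set(TARGET_CLASSES)
    )
    classes = [c for c in classes if c and c != "none"]
    for cls in classes:
        mine = [r for r in recs
                if getattr(r, "cls", getattr(r, "label", None)) == cls]
        imgs = {r.image_id for r in mine}
        rows.append(dict(
            **{"class": cls},
            total=len(mine),
            encounter_images=len(imgs),
            encounter_fraction=len(imgs) / n_images,
        ))
    return pd.DataFrame(rows, columns=["class", "total", "encounter_images",
                                       "encounter_fraction"])


# ---------------------------------------------------------------------------
# manual-review round trip


def export_review(
    detections: Sequence[Detection],
    crops: dict[tuple[str, int], np.ndarray],
    out_dir: str | Path,
) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """Write per-class crop folders plus an editable keep/discard CSV.

    ``crops`` maps (image_id, roi_id) to the grayscale crop.  Missing crops
    are listed in the return value, not fatal — the CSV row is still written
    so the reviewer sees the full detection set.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    rows = []
    missing = []
    for d in detections:
        if d.label == "none":
            continue
        cls_dir = out / d.label
        cls_dir.mkdir(parents=True, exist_ok=True)
        fname = f"{d.image_id}_roi{d.roi_id:04d}.png"
        key = (d.image_id, d.roi_id)
        if key in crops:
            iio.imwrite(cls_dir / fname, np.asarray(crops[key], dtype=np.uint8))
        else:
            missing.append(key)
        rows.append(dict(
            image_id=d.image_id, roi_id=d.roi_id, **{"class": d.label},
            top=d.top, left=d.left, height=d.height, width=d.width,
            crop=str(Path(d.label) / fname), keep=1,
        ))
    df = pd.DataFrame(rows, columns=["image_id", "roi_id", "class", "top",
                                     "left", "height", "width", "crop", "keep"])
    df.to_csv(out / "review.csv", index=False)
    return df, missing


def apply_review(
    detections: Sequence[Detection], review: pd.DataFrame | str | Path
) -> list[Detection]:
    """Drop detections the reviewer marked keep=0."""
    if not isinstance(review, pd.DataFrame):
        review = pd.read_csv(review)
    discard = {
        (str(r["image_id"]), int(r["roi_id"]))
        for _, r in review.iterrows()
        if int(r["keep"]) == 0
    }
    return [
        d for d in detections
        if d.label == "none" or (d.image_id, d.roi_id) not in discard
    ]
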