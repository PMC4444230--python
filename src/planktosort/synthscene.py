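"""Synthetic shadowgraph scenes with ground truth.

Shadowgraph systems image a backlit volume of water: organisms and suspended
particulates appear as dark silhouettes on a bright, non-uniformly illuminated
field.  In turbid estuarine water a single frame carries hundreds to thousands
of particulates, and the organisms of interest (copepods, chaetognaths /
"arrow-like" bodies, gelatinous zooplankton) make up only a few percent of the
segmentable objects.  This module generates frames with exactly that
statistical structure, together with exhaustive per-object ground truth, so
the segmentation / feature / classification stages can be exercised and scored
without access to an instrument.

Objects are rendered as transmittance stamps (1 = fully transparent) and
composited multiplicatively onto an illumination-modulated background, so
contrast scales with the local background the way real silhouettes do.
Overlapping placements are allowed on purpose — merged objects are a known
failure mode of segmentation in this regime and the tests must exercise it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CLASSES = ("copepod", "arrow", "gelatinous", "bubble", "particulate")
TARGET_CLASSES = ("copepod", "arrow", "gelatinous")

#: Full-scale characteristic sizes in pixels at ~10 um/px (major axis for
#: elongated bodies, diameter for round ones).  A copepod of 0.8-1.8 mm, an
#: arrow worm of 4-9 mm, a gelatinous body of 1.6-3.8 mm across, bubbles from
#: near-surface propeller wash, and fine suspended detritus.
SIZE_RANGES: dict[str, tuple[float, float]] = {
    "copepod": (80.0, 180.0),
    "arrow": (400.0, 900.0),
    "gelatinous": (160.0, 380.0),
    "bubble": (60.0, 200.0),
    "particulate": (8.0, 44.0),
}

_MIN_SIZE = 5.0


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic frame.

    ``scale`` multiplies the full-scale size ranges so that quarter-scale
    (612x512) frames carry proportionally smaller organisms.  ``target_cap``,
    when not None, enforces that target objects stay below that fraction of
    all placed objects (the regime the classifier is designed for).
    """

    width: int = 2448
    height: int = 2050
    background_level: float = 180.0
    illumination: float = 0.15
    noise_sigma: float = 4.0
    n_particulates: int = 800
    n_copepod: int = 2
    n_arrow: int = 0
    n_gelatinous: int = 0
    n_bubble: int = 5
    target_cap: float | None = 0.05
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 256 or self.height < 256:
            raise ValueError("frame must be at least 256x256")
        for name in ("n_particulates", "n_copepod", "n_arrow", "n_gelatinous", "n_bubble"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.illumination < 1.0:
            raise ValueError("illumination amplitude must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 < self.scale <= 4:
            raise ValueError("scale out of range")
        if self.target_cap is not None:
            n_target = self.n_copepod + self.n_arrow + self.n_gelatinous
            total = n_target + self.n_bubble + self.n_particulates
            if total > 0 and n_target > self.target_cap * total:
                raise ValueError(
                    f"target objects ({n_target}) exceed {self.target_cap:.0%} "
                    f"of all objects ({total})"
                )

    @property
    def n_objects(self) -> int:
        return (
            self.n_particulates
            + self.n_copepod
            + self.n_arrow
            + self.n_gelatinous
            + self.n_bubble
        )

    @classmethod
    def quarter(cls, **kwargs) -> "SceneConfig":
        """Quarter-linear-scale preset (612x512) used for desk-scale runs."""
        defaults = dict(width=612, height=512, scale=0.25, n_particulates=200)
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass(frozen=True)
class ObjectTruth:
    """Ground truth for one placed object (0-based, half-open bbox)."""

    object_id: int
    cls: str
    row: float
    col: float
    top: int
    left: int
    height: int
    width: int
    area: int
    image_id: str = ""

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        return (self.top, self.left, self.height, self.width)


@dataclass
class Scene:
    image_id: str
    image: np.ndarray
    truth: list[ObjectTruth]
    config: SceneConfig = None


def _odd_canvas(extent: float) -> int:
    n = int(np.ceil(extent)) + 5
    return n + 1 if n % 2 == 0 else n


def _rot_grid(n: int, orientation: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotated coordinates (u along the body axis, v across) on an odd square
    canvas centred at the middle pixel.  Near-exact multiples of pi/2 are
    snapped so that pure rotations map the pixel grid onto itself."""
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    yy -= c
    xx -= c
    co, si = np.cos(orientation), np.sin(orientation)
    if abs(co) < 1e-12:
        co = 0.0
    if abs(si) < 1e-12:
        si = 0.0
    u = co * xx + si * yy
    v = -si * xx + co * yy
    return u, v


def render_object(
    kind: str,
    size_px: float,
    orientation: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one object as a grayscale stamp plus binary support.

    The stamp encodes transmittance against a nominal white field: a value of
    255 is fully transparent, lower values are proportionally darker.  The
    support marks pixels where the object attenuates light at all.  Opaque
    parts are therefore always darker than any background they land on.
    """
    if kind not in CLASSES:
        raise ValueError(f"unknown object kind: {kind!r}")
    if size_px < _MIN_SIZE:
        raise ValueError(f"size_px must be >= {_MIN_SIZE}")
    if rng is None:
        rng = np.random.default_rng(0)

    if kind == "arrow":
        n = _odd_canvas(size_px * 1.1)
        u, v = _rot_grid(n, orientation)
        half_len = size_px / 2.0
        # spindle-shaped body, symmetric along and across the axis, >=5:1 aspect
        half_w = (size_px / 18.0) * np.sqrt(np.clip(1.0 - (u / half_len) ** 2, 0.0, None))
        trans = np.ones((n, n))
        body = (np.abs(u) <= half_len) & (np.abs(v) <= half_w)
        trans[body] = 0.35
    elif kind == "copepod":
        n = _odd_canvas(size_px * 1.9)
        u, v = _rot_grid(n, orientation)
        a = size_px / 2.0
        b = a * 0.35
        trans = np.ones((n, n))
        body = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        # 1-2 thin antennae sweeping forward from the head
        n_ant = int(rng.integers(1, 3))
        ant_len = 0.75 * size_px
        ant_w = max(1.0, size_px / 40.0)
        ant = np.zeros((n, n), dtype=bool)
        for sgn in ([1, -1][:n_ant]):
            phi = np.deg2rad(25.0) * sgn
            du, dv = -np.cos(phi), np.sin(phi)
            # distance from (u, v) to the segment starting at the head (-a, 0)
            pu, pv = u + a, v
            t = np.clip(pu * du + pv * dv, 0.0, ant_len)
            dist = np.hypot(pu - t * du, pv - t * dv)
            ant |= dist <= ant_w / 2.0
        trans[ant] = 0.55
        trans[body] = 0.25
    elif kind == "gelatinous":
        n = _odd_canvas(size_px * 1.35)
        u, v = _rot_grid(n, orientation)
        rho = np.hypot(u, v)
        theta = np.arctan2(v, u)
        n_lobes = int(rng.integers(4, 7))
        phase = float(rng.uniform(0, 2 * np.pi))
        r_out = (size_px / 2.0) * (1.0 + 0.14 * np.cos(n_lobes * theta + phase))
        trans = np.ones((n, n))
        body = rho <= r_out
        margin = body & (rho > 0.82 * r_out)
        trans[body] = 0.88          # translucent mesoglea
        trans[margin] = 0.76        # denser bell margin
        # internal structures (gut / canals) of a distinctly higher opacity
        n_org = int(rng.integers(2, 5))
        for _ in range(n_org):
            orho = float(rng.uniform(0.1, 0.45)) * size_px / 2.0
            oth = float(rng.uniform(0, 2 * np.pi))
            ou, ov = orho * np.cos(oth), orho * np.sin(oth)
            oa = float(rng.uniform(0.08, 0.18)) * size_px
            ob = oa * float(rng.uniform(0.35, 0.8))
            organ = ((u - ou) / oa) ** 2 + ((v - ov) / ob) ** 2 <= 1.0
            trans[organ & body] = 0.62
    elif kind == "bubble":
        n = _odd_canvas(size_px * 1.1)
        u, v = _rot_grid(n, orientation)
        rho = np.hypot(u, v)
        r = size_px / 2.0
        trans = np.ones((n, n))
        ring = (rho <= r) & (rho > 0.62 * r)
        trans[ring] = 0.45          # dark refractive ring, bright open centre
    else:  # particulate
        n = _odd_canvas(size_px * 1.4)
        u, v = _rot_grid(n, orientation)
        rho = np.hypot(u, v)
        theta = np.arctan2(v, u)
        # irregular outline from a few random Fourier modes, single opacity
        r = (size_px / 2.0) * np.ones_like(theta)
        for mode in (2, 3, 5):
            r = r * (1.0 + 0.18 * float(rng.uniform(-1, 1)) * np.cos(mode * theta + float(rng.uniform(0, 2 * np.pi))))
        trans = np.ones((n, n))
        blob = rho <= np.maximum(r, 1.0)
        trans[blob] = float(rng.uniform(0.30, 0.55))

    support = trans < 1.0 - 1e-9
    stamp = 255.0 * trans
    return stamp, support


def illumination_field(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field: radial vignette plus a tilted gradient.

    Draws two numbers from ``rng`` (the gradient direction), so callers that
    reproduce a scene must consume the generator in the same order as
    :func:`generate_scene`.
    """
    h, w = config.height, config.width
    yy = (np.arange(h, dtype=float)[:, None] / (h - 1)) * 2.0 - 1.0
    xx = (np.arange(w, dtype=float)[None, :] / (w - 1)) * 2.0 - 1.0
    radial = (xx**2 + yy**2) / 2.0
    gx, gy = rng.uniform(-1.0, 1.0, size=2)
    tilt = 0.5 * (gx * xx + gy * yy) + 0.5
    a = config.illumination
    return 1.0 - a * (0.65 * radial + 0.35 * tilt)


def generate_scene(config: SceneConfig, image_id: str = "scene_0000") -> Scene:
    """Generate one frame and its truth table; bit-identical for equal
    (config, seed)."""
    rng = np.random.default_rng(config.seed)
    field_ = illumination_field(config, rng)
    scene = config.background_level * field_

    order: list[str] = (
        ["copepod"] * config.n_copepod
        + ["arrow"] * config.n_arrow
        + ["gelatinous"] * config.n_gelatinous
        + ["bubble"] * config.n_bubble
        + ["particulate"] * config.n_particulates
    )
    truths: list[ObjectTruth] = []
    h, w = config.height, config.width
    for obj_id, kind in enumerate(order):
        lo, hi = SIZE_RANGES[kind]
        size = max(_MIN_SIZE, float(rng.uniform(lo, hi)) * config.scale)
        orientation = float(rng.uniform(0, np.pi))
        stamp, support = render_object(kind, size, orientation, rng)
        n = stamp.shape[0]
        if n > h or n > w:
            raise ValueError(
                f"object {kind} (canvas {n}px) does not fit in {w}x{h} frame"
            )
        top = int(rng.integers(0, h - n + 1))
        left = int(rng.integers(0, w - n + 1))
        scene[top : top + n, left : left + n] *= stamp / 255.0

        rows, cols = np.nonzero(support)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        truths.append(
            ObjectTruth(
                object_id=obj_id,
                cls=kind,
                row=float(rows.mean() + top),
                col=float(cols.mean() + left),
                top=int(top + r0),
                left=int(left + c0),
                height=int(r1 - r0),
                width=int(c1 - c0),
                area=int(support.sum()),
                image_id=image_id,
            )
        )

    if config.noise_sigma > 0:
        scene = scene + rng.normal(0.0, config.noise_sigma, scene.shape)
    image = np.clip(np.rint(scene), 0, 255).astype(np.uint8)
    return Scene(image_id=image_id, image=image, truth=truths, config=config)


def truth_to_dataframe(truths: Iterable[ObjectTruth]) -> pd.DataFrame:
    rows = [
        dict(
            image_id=t.image_id,
            object_id=t.object_id,
            **{"class": t.cls},
            row=t.row,
            col=t.col,
            top=t.top,
            left=t.left,
            height=t.height,
            width=t.width,
            area=t.area,
        )
        for t in truths
    ]
    cols = ["image_id", "object_id", "class", "row", "col",
            "top", "left", "height", "width", "area"]
    return pd.DataFrame(rows, columns=cols)


def write_scenes(scenes: Sequence[Scene], out_dir: str | Path) -> None:
    """Write scenes as 8-bit PNGs plus one truth CSV."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sc in scenes:
        iio.imwrite(out / f"{sc.image_id}.png", sc.image)
    truth_to_dataframe([t for sc in scenes for t in sc.truth]).to_csv(
        out / "truth.csv", index=False
    )


def read_truth(path: str | Path) -> list[ObjectTruth]:
    df = pd.read_csv(path)
    return [
        ObjectTruth(
            object_id=int(r["object_id"]),
            cls=str(r["class"]),
            row=float(r["row"]),
            col=float(r["col"]),
            top=int(r["top"]),
            left=int(r["left"]),
            height=int(r["height"]),
            width=int(r["width"]),
            area=int(r["area"]),
            image_id=str(r["image_id"]),
        )
        for _, r in df.iterrows()
    ]


def _bbox_iou(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> float:
    top = max(a[0], b[0])
    left = max(a[1], b[1])
    bottom = min(a[0] + a[2], b[0] + b[2])
    right = min(a[1] + a[3], b[1] + b[3])
    if bottom <= top or right <= left:
        return 0.0
    inter = (bottom - top) * (right - left)
    return inter / (a[2] * a[3] + b[2] * b[3] - inter)


def _crop_with_margin(image: np.ndarray, t: ObjectTruth) -> np.ndarray:
    m = max(2, int(round(0.08 * max(t.height, t.width))))
    r0 = max(0, t.top - m)
    c0 = max(0, t.left - m)
    r1 = min(image.shape[0], t.top + t.height + m)
    c1 = min(image.shape[1], t.left + t.width + m)
    return image[r0:r1, c0:c1].copy()


#: library quota per class at level 1 (representative target exemplars)
LEVEL1_LIBRARY_SIZES = {"arrow": 80, "copepod": 65, "gelatinous": 65}
#: level-2 library: targets vs non-targets per group (~6-8% minority ratio)
LEVEL2_TARGETS = 65
LEVEL2_NONTARGETS = 985


@dataclass
class Benchmark:
    train_scenes: list[Scene]
    test_scenes: list[Scene]
    library: "object"  # planktosort.classifier.TrainingLibrary


def generate_benchmark(
    config: SceneConfig,
    n_scenes: int,
    seed: int,
    *,
    n_train: int = 45,
    train_config: SceneConfig | None = None,
    level1_sizes: dict[str, int] | None = None,
    level2_targets: int = LEVEL2_TARGETS,
    level2_nontargets: int = LEVEL2_NONTARGETS,
    segmenter=None,
    match_iou: float = 0.3,
) -> Benchmark:
    """Scenes plus a labeled crop library with the study's class imbalance.

    ``n_scenes`` held-out test scenes are drawn from ``config``; ``n_train``
    training scenes come from ``train_config`` (default: a target-richer mix,
    still below the 5% cap — the analog of hand-selecting frames that contain
    organisms when building a library).  Target crops fill the per-class
    level-1 quotas; level-2 non-target crops are sampled from particulate and
    bubble objects, one independent draw per group.  Scene i is generated
    from substream seed+i, so split membership is reproducible.

    By default crops are cut from ground-truth bounding boxes.  When a
    ``segmenter`` callable (image -> list of ROIs) is supplied, crops are
    instead harvested from segmented ROIs — a target exemplar is an ROI
    reaching ``match_iou`` bbox IoU with a truth organism, a non-target
    exemplar an ROI overlapping no organism at all — which emulates cropping
    the ROIs a real pipeline produces and keeps the library on the same
    distribution the classifier will see.
    """
    from .classifier import TrainingLibrary

    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    level1_sizes = dict(level1_sizes or LEVEL1_LIBRARY_SIZES)
    if train_config is None:
        train_config = replace(
            config, n_copepod=3, n_arrow=3, n_gelatinous=3, n_bubble=3
        )

    train_scenes = [
        generate_scene(
            replace(train_config, seed=seed + i), image_id=f"train_{i:04d}"
        )
        for i in range(n_train)
    ]
    test_scenes = [
        generate_scene(
            replace(config, seed=seed + n_train + i), image_id=f"test_{i:04d}"
        )
        for i in range(n_scenes)
    ]

    target_crops: dict[str, list[np.ndarray]] = {c: [] for c in TARGET_CLASSES}
    nontarget_pool: list[np.ndarray] = []
    if segmenter is None:
        for sc in train_scenes:
            for t in sc.truth:
                if t.cls in TARGET_CLASSES:
                    target_crops[t.cls].append(_crop_with_margin(sc.image, t))
                else:
                    nontarget_pool.append(_crop_with_margin(sc.image, t))
    else:
        for sc in train_scenes:
            targets = [t for t in sc.truth if t.cls in TARGET_CLASSES]
            for roi in segmenter(sc.image):
                rb = (roi.top, roi.left, roi.height, roi.width)
                best_iou, best_cls = 0.0, None
                for t in targets:
                    iou = _bbox_iou(rb, t.bbox)
                    if iou > best_iou:
                        best_iou, best_cls = iou, t.cls
                if best_iou >= match_iou:
                    target_crops[best_cls].append(roi.crop.copy())
                elif best_iou <= 0.05:
                    nontarget_pool.append(roi.crop.copy())
                # partial overlaps are ambiguous and used for neither side

    for cls, want in level1_sizes.items():
        have = len(target_crops[cls])
        if have < min(want, level2_targets):
            raise ValueError(
                f"training scenes yielded only {have} {cls} crops; "
                f"increase n_train"
            )

    rng = np.random.default_rng(seed + 990_000)
    level1 = {c: target_crops[c][: level1_sizes[c]] for c in TARGET_CLASSES}
    level2 = {}
    for c in TARGET_CLASSES:
        # "ROIs that do not contain a <c>": other organisms count as much as
        # detritus — they are exactly the confusable non-targets the group
        # classifier must learn to reject.
        others = [
            crop
            for oc in TARGET_CLASSES
            if oc != c
            for crop in target_crops[oc][: level1_sizes[oc]]
        ]
        n_pool = min(max(level2_nontargets - len(others), 0), len(nontarget_pool))
        idx = rng.choice(len(nontarget_pool), size=n_pool, replace=False)
        level2[c] = (
            target_crops[c][:level2_targets],
            others + [nontarget_pool[int(i)] for i in idx],
        )
    library = TrainingLibrary(level1=level1, level2=level2)
    return Benchmark(train_scenes=train_scenes, test_scenes=test_scenes, library=library)
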