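"""Hybrid binarization and ROI extraction for shadowgraph frames.

Two complementary detectors are combined:

* Sauvola local adaptive thresholding, tuned for small solid-dark bodies
  (copepods) under non-uniform illumination: per pixel,
  ``T(i,j) = m(i,j) * (1 + k*(s(i,j)/R - 1))`` with windowed mean ``m`` and
  standard deviation ``s``; a pixel is foreground iff its intensity is below
  ``T`` (dark-object polarity).
* Maximally stable extremal regions (MSER) with dark polarity for large
  bodies (gelatinous zooplankton), whose translucent parts defeat any single
  threshold but form components that stay nearly constant across a range of
  thresholds.  Only regions above an area gate (default 5000 px, ~0.5 mm^2
  at 10 um/px) are kept.

The union of the two masks is decomposed into 8-connected components; each
component becomes an ROI carrying bbox, area, ellipse-equivalent axis lengths
and its grayscale crop.

A global Otsu threshold (between-class variance on a smoothed gray histogram)
is also provided: it drives ROI-level denoising downstream and is logged as a
per-frame contrast diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit
from scipy import ndimage

_EIGHT = np.ones((3, 3), dtype=int)


# ---------------------------------------------------------------------------
# Otsu


@dataclass(frozen=True)
class OtsuResult:
    t_star: int
    sigma_b2: float
    w0: float
    w1: float
    mu0: float
    mu1: float
    mu_t: float
    degenerate: bool = False


def otsu_global(image: np.ndarray, smooth_window: int = 5) -> OtsuResult:
    """Global threshold maximizing between-class variance.

    The 256-bin histogram is smoothed by a centered moving average of width
    ``smooth_window`` (reflected ends) and renormalized before the scan.
    Ties break toward the smallest threshold; a zero-variance (constant)
    image returns its own gray value flagged degenerate.
    """
    if image.size == 0:
        raise ValueError("empty image")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    flat = np.asarray(image, dtype=np.int64).ravel()
    if flat.min() == flat.max():
        g = int(flat[0])
        return OtsuResult(
            t_star=g, sigma_b2=0.0, w0=1.0, w1=0.0,
            mu0=float(g), mu1=float(g), mu_t=float(g), degenerate=True,
        )
    hist = np.bincount(flat, minlength=256)[:256].astype(float)
    if smooth_window > 1:
        r = smooth_window // 2
        padded = np.pad(hist, r, mode="reflect")
        hist = np.convolve(padded, np.ones(smooth_window) / smooth_window, mode="valid")
    p = hist / hist.sum()

    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    mcum = np.cumsum(p * levels)
    mu_t = mcum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, mcum / w0, 0.0)
        mu1 = np.where(w1 > 0, (mu_t - mcum) / w1, 0.0)
    sigma = w0 * (mu0 - mu_t) ** 2 + w1 * (mu1 - mu_t) ** 2
    sigma[w0 <= 0] = 0.0
    sigma[w1 <= 0] = 0.0

    t = int(np.argmax(sigma))
    s = float(sigma[t])
    degenerate = s <= 1e-12
    if degenerate:
        t = int(round(mu_t))
        return OtsuResult(
            t_star=t, sigma_b2=0.0, w0=1.0, w1=0.0,
            mu0=mu_t, mu1=mu_t, mu_t=float(mu_t), degenerate=True,
        )
    return OtsuResult(
        t_star=t,
        sigma_b2=s,
        w0=float(w0[t]),
        w1=float(w1[t]),
        mu0=float(mu0[t]),
        mu1=float(mu1[t]),
        mu_t=float(mu_t),
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# Sauvola


@dataclass(frozen=True)
class SauvolaParams:
    window: int = 77
    k: float = 0.6
    R: float = 128.0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.R <= 0:
            raise ValueError("R must be > 0")


def _window_sums(padded: np.ndarray, window: int) -> np.ndarray:
    """Exact integer window sums via a 2-D integral image."""
    ii = np.zeros(
        (padded.shape[0] + 1, padded.shape[1] + 1), dtype=np.int64
    )
    np.cumsum(np.cumsum(padded, axis=0), axis=1, out=ii[1:, 1:])
    w = window
    return ii[w:, w:] - ii[:-w, w:] - ii[w:, :-w] + ii[:-w, :-w]


def sauvola_threshold(image: np.ndarray, params: SauvolaParams) -> np.ndarray:
    """Per-pixel Sauvola threshold surface (reflect-padded borders)."""
    h, w = image.shape
    if params.window > min(h, w):
        raise ValueError("window larger than image")
    r = params.window // 2
    padded = np.pad(np.asarray(image, dtype=np.int64), r, mode="reflect")
    n = params.window * params.window
    s1 = _window_sums(padded, params.window)
    s2 = _window_sums(padded * padded, params.window)
    m = s1 / n
    var = s2 / n - m * m
    s = np.sqrt(np.maximum(var, 0.0))
    return m * (1.0 + params.k * (s / params.R - 1.0))


def sauvola_mask(image: np.ndarray, params: SauvolaParams | None = None) -> np.ndarray:
    """Binary mask of dark objects: pixel foreground iff intensity < T(i,j)."""
    params = params or SauvolaParams()
    t = sauvola_threshold(image, params)
    return np.asarray(image, dtype=float) < t


# ---------------------------------------------------------------------------
# MSER


@dataclass(frozen=True)
class MserParams:
    delta: int = 2
    max_variation: float = 0.5
    min_area: int = 5000
    #: regions above this area are never reported (None: 5% of the frame).
    #: Without an upper gate, slowly-varying illumination yields huge
    #: "stable" regions (the whole frame is trivially stable at the top of
    #: the gray range, dark corners at intermediate levels); the largest
    #: gelatinous body spans well under 5% of a frame.
    max_area: int | None = None

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if self.max_variation <= 0:
            raise ValueError("max_variation must be > 0")
        if self.min_area <= 0:
            raise ValueError("min_area must be > 0")


@njit(cache=True)
def _max_tree_parent(flat: np.ndarray, order: np.ndarray, w: int, h: int) -> np.ndarray:
    """Component-tree parent array (max-tree, 8-connectivity).

    Union-find flooding from the highest value down (Berger et al.'s
    algorithm): each pixel becomes the current representative of its zone;
    merging attaches the previous representative below the new pixel.
    """
    n = flat.size
    parent = np.full(n, -1, dtype=np.int64)
    root = np.full(n, -1, dtype=np.int64)
    rank = np.zeros(n, dtype=np.int32)
    repr_ = np.zeros(n, dtype=np.int64)
    for oi in range(n - 1, -1, -1):
        p = order[oi]
        parent[p] = p
        root[p] = p
        repr_[p] = p
        y = p // w
        x = p % w
        for dy in range(-1, 2):
            for dx in range(-1, 2):
                if dy == 0 and dx == 0:
                    continue
                ny = y + dy
                nx = x + dx
                if ny < 0 or ny >= h or nx < 0 or nx >= w:
                    continue
                q = ny * w + nx
                if parent[q] < 0:
                    continue
                r1 = p
                while root[r1] != r1:
                    r1 = root[r1]
                r2 = q
                while root[r2] != r2:
                    r2 = root[r2]
                a = p
                while root[a] != r1:
                    b = root[a]
                    root[a] = r1
                    a = b
                a = q
                while root[a] != r2:
                    b = root[a]
                    root[a] = r2
                    a = b
                if r1 != r2:
                    parent[repr_[r2]] = p
                    if rank[r1] < rank[r2]:
                        r1, r2 = r2, r1
                    root[r2] = r1
                    if rank[r1] == rank[r2]:
                        rank[r1] += 1
                    repr_[r1] = p
    return parent


def _canonical_pointers(parent: np.ndarray, val: np.ndarray) -> np.ndarray:
    """Map every component-tree node to its canonical representative
    (the highest node of its flat zone) by pointer doubling."""
    is_canon = (parent == np.arange(parent.size)) | (val[parent] != val)
    f = np.where(is_canon, np.arange(parent.size), parent)
    while True:
        f2 = f[f]
        if np.array_equal(f2, f):
            return f
        f = f2


def mser_large(image: np.ndarray, params: MserParams | None = None) -> list[np.ndarray]:
    """Dark-polarity maximally stable extremal regions above the area gate.

    Built on the component tree (max-tree of the inverted image): every
    canonical node is a candidate region; its variation is the relative area
    growth when the threshold is raised by ``delta`` gray levels.  Candidates
    must exceed ``min_area`` and stay below ``max_variation``; nested
    duplicates collapse to the most stable representative (ties by larger
    area, so a whole translucent body wins over an equally stable organ
    inside it).  Returns full-frame boolean masks.
    """
    params = params or MserParams()
    image = np.asarray(image)
    inv = (255 - image.astype(np.int64)).ravel()
    h, w = image.shape
    order = np.argsort(inv, kind="stable")
    parent = _max_tree_parent(inv, order, w, h)
    n = parent.size
    max_area = params.max_area if params.max_area is not None else n // 20

    canon = _canonical_pointers(parent, inv)
    area = np.bincount(canon, minlength=n).astype(np.int64)
    nodes = np.flatnonzero(
        (parent == np.arange(n)) | (inv[parent] != inv)
    )
    pc = canon[parent[nodes]]  # canonical parent of each canonical node
    parent_of: dict[int, int] = dict(zip(nodes.tolist(), pc.tolist()))
    # accumulate subtree areas level by level (children strictly deeper)
    lv = inv[nodes]
    for level in np.unique(lv)[::-1]:
        grp = nodes[lv == level]
        par = canon[parent[grp]]
        keep = par != grp  # root maps to itself
        np.add.at(area, par[keep], area[grp[keep]])

    root = int(np.flatnonzero(parent == np.arange(n))[0])
    candidates = []
    for node in nodes:
        if area[node] <= params.min_area or area[node] > max_area:
            continue
        if int(node) == root:
            continue
        v = int(inv[node])
        birth = 255 - v  # original-image threshold at which this region appears
        # component containing this region at threshold birth+delta
        a = int(node)
        while True:
            p = parent_of[a]
            if p == a:
                break
            if (255 - int(inv[p])) <= birth + params.delta:
                a = p
            else:
                break
        variation = (float(area[a]) - float(area[node])) / float(area[node])
        if variation <= params.max_variation:
            candidates.append((int(node), birth, variation, int(area[node])))

    if not candidates:
        return []

    # ancestor chains (canonical) for nested-duplicate suppression
    chains: dict[int, frozenset[int]] = {}
    for node, *_ in candidates:
        chain = set()
        a = node
        while True:
            p = parent_of[a]
            if p == a:
                break
            chain.add(p)
            a = p
        chains[node] = frozenset(chain)

    # most stable first; among comparably stable nested regions prefer the
    # larger (keeps whole bodies over their internal structures)
    candidates.sort(key=lambda c: (int(c[2] / 0.1), -c[3], c[0]))
    accepted: list[tuple[int, int]] = []
    accepted_ids: set[int] = set()
    accepted_chain_union: set[int] = set()
    for node, birth, variation, _a in candidates:
        if chains[node] & accepted_ids:
            continue  # nested inside an accepted region
        if node in accepted_chain_union:
            continue  # an accepted region is nested inside this one
        accepted.append((node, birth))
        accepted_ids.add(node)
        accepted_chain_union |= chains[node]

    masks = []
    for node, birth in sorted(accepted, key=lambda c: c[0]):
        thr = image <= birth
        lbl, _ = ndimage.label(thr, structure=_EIGHT)
        masks.append(lbl == lbl.ravel()[node])
    return masks


# ---------------------------------------------------------------------------
# mask combination and ROI extraction


def combine_masks(small: np.ndarray, large_regions: Sequence[np.ndarray]) -> np.ndarray:
    """Pixel-wise union of the adaptive-threshold mask and all MSER regions."""
    out = np.asarray(small, dtype=bool).copy()
    for m in large_regions:
        if m.shape != out.shape:
            raise ValueError("mask shape mismatch")
        out |= np.asarray(m, dtype=bool)
    return out


@dataclass
class ROI:
    """One connected component: geometry plus its grayscale crop.

    Bounding boxes are 0-based half-open; axis lengths come from the
    second-moment equivalent ellipse with a 1/12-per-pixel variance
    correction (pixels treated as unit squares), which keeps the minor axis
    strictly positive even for 1-pixel-wide components.
    """

    id: int
    top: int
    left: int
    height: int
    width: int
    area: int
    major_axis: float
    minor_axis: float
    crop: np.ndarray
    mask: np.ndarray  # crop-local support of the component

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        return (self.top, self.left, self.height, self.width)


def _ellipse_axes(mask: np.ndarray) -> tuple[float, float]:
    rows, cols = np.nonzero(mask)
    r = rows - rows.mean()
    c = cols - cols.mean()
    n = r.size
    cov = np.array(
        [
            [np.dot(r, r) / n + 1.0 / 12.0, np.dot(r, c) / n],
            [np.dot(r, c) / n, np.dot(c, c) / n + 1.0 / 12.0],
        ]
    )
    ev = np.linalg.eigvalsh(cov)
    minor, major = 4.0 * np.sqrt(np.maximum(ev, 0.0))
    return float(major), float(minor)


def extract_rois(
    mask: np.ndarray, image: np.ndarray, min_roi_area: int = 50
) -> list[ROI]:
    """8-connected components of the mask, in top-left scan order."""
    if mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    lbl, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return []
    slices = ndimage.find_objects(lbl)
    counts = np.bincount(lbl.ravel(), minlength=n + 1)
    rois: list[ROI] = []
    rid = 0
    for i, sl in enumerate(slices, start=1):
        if counts[i] < min_roi_area:
            continue
        local = lbl[sl] == i
        major, minor = _ellipse_axes(local)
        rois.append(
            ROI(
                id=rid,
                top=sl[0].start,
                left=sl[1].start,
                height=sl[0].stop - sl[0].start,
                width=sl[1].stop - sl[1].start,
                area=int(counts[i]),
                major_axis=major,
                minor_axis=minor,
                crop=np.asarray(image[sl]).copy(),
                mask=local,
            )
        )
        rid += 1
    return rois


def _bbox_intersection(a: ROI, b: ROI) -> int:
    top = max(a.top, b.top)
    left = max(a.left, b.left)
    bottom = min(a.top + a.height, b.top + b.height)
    right = min(a.left + a.width, b.left + b.width)
    if bottom <= top or right <= left:
        return 0
    return (bottom - top) * (right - left)


def deduplicate_rois(rois: Sequence[ROI], overlap_threshold: float = 0.8) -> list[ROI]:
    """Drop ROIs whose bbox overlap-over-min-area with a larger kept ROI
    reaches the threshold (fragments of an already-kept object)."""
    if not 0 < overlap_threshold <= 1:
        raise ValueError("overlap_threshold must be in (0, 1]")
    order = sorted(rois, key=lambda r: (-r.area, r.top, r.left))
    kept: list[ROI] = []
    for roi in order:
        bbox_area = roi.height * roi.width
        dup = False
        for k in kept:
            inter = _bbox_intersection(roi, k)
            denom = min(bbox_area, k.height * k.width)
            if denom > 0 and inter / denom >= overlap_threshold:
                dup = True
                break
        if not dup:
            kept.append(roi)
    return sorted(kept, key=lambda r: (r.top, r.left, r.id))


# ---------------------------------------------------------------------------
# k calibration


def _roi_overlaps_truth(roi: ROI, truth, iou_min: float) -> bool:
    top = max(roi.top, truth.top)
    left = max(roi.left, truth.left)
    bottom = min(roi.top + roi.height, truth.top + truth.height)
    right = min(roi.left + roi.width, truth.left + truth.width)
    if bottom <= top or right <= left:
        return False
    inter = (bottom - top) * (right - left)
    union = roi.height * roi.width + truth.height * truth.width - inter
    return inter / union >= iou_min


def calibrate_k(
    scenes: Sequence,
    grid: Sequence[float],
    params: SauvolaParams | None = None,
    *,
    min_roi_area: int = 50,
    target_class: str = "copepod",
    iou_min: float = 0.1,
) -> tuple[float, list[tuple[float, int]]]:
    """Pick the Sauvola sensitivity k that misses the fewest target organisms.

    For each k the annotated frames are binarized and ROIs extracted; a truth
    target counts as missed when no ROI reaches ``iou_min`` bbox IoU with it
    (plain pixel overlap would reward tiny k, where background texture floods
    into one giant component that "touches" everything).  Ties break toward
    the smaller k.  ``scenes`` are objects with ``.image`` and ``.truth``.
    """
    if len(grid) == 0:
        raise ValueError("empty k grid")
    base = params or SauvolaParams()
    targets = [
        (i, t)
        for i, sc in enumerate(scenes)
        for t in sc.truth
        if t.cls == target_class
    ]
    if not targets:
        raise ValueError("no annotated target objects")
    table: list[tuple[float, int]] = []
    for k in grid:
        p = replace(base, k=float(k))
        rois_per_scene = [
            extract_rois(sauvola_mask(sc.image, p), sc.image, min_roi_area)
            for sc in scenes
        ]
        misses = sum(
            not any(_roi_overlaps_truth(r, t, iou_min) for r in rois_per_scene[i])
            for i, t in targets
        )
        table.append((float(k), misses))
    best = min(table, key=lambda kt: (kt[1], kt[0]))
    return best[0], table
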