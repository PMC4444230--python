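"""ROI denoising, size normalization and HOG shape descriptors.

A segmented crop usually carries bystander particulates next to the organism
of interest.  Denoising keeps the grayscale of the largest connected dark
component (internal texture matters, especially for gelatinous bodies whose
tissue opacity varies) and neutralizes every other component to the crop's
background mean.  Crops are then padded to square with that background mean
(no step edges for the gradient operator to latch onto), resampled to a fixed
side, and described by a histogram-of-oriented-gradients vector.

HOG layout: centered [-1, 0, 1] differences with replicated borders; unsigned
orientations on [0, 180) split bilinearly by gradient magnitude into ``bins``
histogram bins whose centers sit at i*180/bins; square cells tiled from the
top-left with partial right/bottom cells discarded; overlapping block
normalization (L2-Hys: L2, clip, renormalize).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage
from skimage.transform import resize

from .segmentation import otsu_global

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class DenoiseResult:
    gray: np.ndarray
    no_foreground: bool = False


def denoise_roi(crop: np.ndarray) -> DenoiseResult:
    """Keep the largest dark component's grayscale, neutralize the rest.

    The crop is binarized with a global Otsu threshold (smooth_window=1; a
    small crop's background is close to uniform, so the plain histogram is
    the right one); foreground is the dark side.  Pixels of the largest
    8-connected foreground component keep their original values bit-exactly;
    all other foreground pixels are set to the rounded mean of the background
    pixels.  If thresholding finds no foreground the crop is returned
    unchanged with a warning flag.
    """
    crop = np.asarray(crop)
    if crop.size == 0:
        raise ValueError("empty crop")
    res = otsu_global(crop, smooth_window=1)
    fg = crop <= res.t_star
    if res.degenerate or not fg.any() or fg.all():
        return DenoiseResult(gray=crop.copy(), no_foreground=True)
    lbl, n = ndimage.label(fg, structure=_EIGHT)
    counts = np.bincount(lbl.ravel())
    counts[0] = 0
    keep = int(np.argmax(counts))
    bg_mean = crop[~fg].mean()
    out = crop.copy()
    out[fg & (lbl != keep)] = np.round(bg_mean).astype(crop.dtype)
    return DenoiseResult(gray=out, no_foreground=False)


def estimate_background(crop: np.ndarray) -> float:
    """Mean gray of the crop's non-foreground (lighter) pixels."""
    res = otsu_global(crop, smooth_window=1)
    bg = crop > res.t_star
    if res.degenerate or not bg.any():
        return float(np.asarray(crop, dtype=float).mean())
    return float(crop[bg].mean())


def normalize_roi(
    crop: np.ndarray, side: int, *, stretch: bool = False
) -> np.ndarray:
    """Resample a crop to ``side`` x ``side``.

    By default the crop is first centred on a square canvas filled with its
    background mean, preserving the content's aspect ratio, then resampled
    with bilinear interpolation.  ``stretch=True`` resamples directly (both
    conventions are plausible readings of how the original ROIs were
    normalized; pad-preserve is the default).
    """
    crop = np.asarray(crop, dtype=float)
    if crop.size == 0:
        raise ValueError("empty crop")
    h, w = crop.shape
    if not stretch and h != w:
        n = max(h, w)
        canvas = np.full((n, n), estimate_background(crop), dtype=float)
        r0 = (n - h) // 2
        c0 = (n - w) // 2
        canvas[r0 : r0 + h, c0 : c0 + w] = crop
        crop = canvas
    if crop.shape == (side, side):
        return crop
    return resize(
        crop, (side, side), order=1, anti_aliasing=False,
        preserve_range=True, mode="edge",
    )


@dataclass(frozen=True)
class HogParams:
    cell: int = 16
    bins: int = 9
    block: int = 2
    block_stride: int = 1
    clip: float = 0.2

    def __post_init__(self) -> None:
        if self.cell < 2:
            raise ValueError("cell must be >= 2")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.block < 1 or self.block_stride < 1:
            raise ValueError("block and block_stride must be >= 1")


@dataclass
class FeatureVector:
    values: np.ndarray
    cells: tuple[int, int]
    bins: int
    block: int
    block_stride: int

    def __len__(self) -> int:
        return self.values.size


def save_descriptor(fv: FeatureVector, path) -> None:
    """Write the flat vector as CSV with a JSON sidecar for the layout."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savetxt(path, fv.values[None, :], delimiter=",", fmt="%.10g")
    meta = dict(cells=list(fv.cells), bins=fv.bins, block=fv.block,
                block_stride=fv.block_stride, length=int(fv.values.size))
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_descriptor(path) -> FeatureVector:
    import json
    from pathlib import Path

    path = Path(path)
    values = np.loadtxt(path, delimiter=",").ravel()
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FeatureVector(values=values, cells=tuple(meta["cells"]),
                         bins=meta["bins"], block=meta["block"],
                         block_stride=meta["block_stride"])


def descriptor_length(side: int, params: HogParams) -> int:
    nc = side // params.cell
    nb = (nc - params.block) // params.block_stride + 1
    if nb < 1:
        raise ValueError("crop smaller than one block")
    return nb * nb * params.block * params.block * params.bins


@njit(cache=True)
def _accumulate_cells(
    padded: np.ndarray, vy: int, vx: int, cell: int, bins: int,
    nc_y: int, nc_x: int,
) -> np.ndarray:
    """Single-pass gradient + bilinear orientation voting into cell bins."""
    hist = np.zeros((nc_y, nc_x, bins))
    bw = np.pi / bins
    for y in range(vy):
        for x in range(vx):
            gx = padded[y + 1, x + 2] - padded[y + 1, x]
            gy = padded[y + 2, x + 1] - padded[y, x + 1]
            mag = np.sqrt(gx * gx + gy * gy)
            if mag == 0.0:
                continue
            theta = np.arctan2(gy, gx) % np.pi
            pos = theta / bw
            j0 = int(np.floor(pos)) % bins
            frac = pos - np.floor(pos)
            cy = y // cell
            cx = x // cell
            hist[cy, cx, j0] += mag * (1.0 - frac)
            hist[cy, cx, (j0 + 1) % bins] += mag * frac
    return hist


def cell_histograms(crop: np.ndarray, params: HogParams) -> np.ndarray:
    """Per-cell orientation histograms, shape (ny, nx, bins).

    Gradients are centred [-1, 0, 1] differences on an edge-padded copy;
    unsigned orientation in [0, pi) splits its magnitude bilinearly between
    the two neighbouring bin centres (at i*pi/bins); partial cells at the
    right/bottom are discarded.
    """
    img = np.asarray(crop, dtype=np.float64)
    h, w = img.shape
    padded = np.pad(img, 1, mode="edge")
    nc_y = h // params.cell
    nc_x = w // params.cell
    return _accumulate_cells(
        padded, nc_y * params.cell, nc_x * params.cell,
        params.cell, params.bins, nc_y, nc_x,
    )


def hog_descriptor(crop: np.ndarray, params: HogParams | None = None) -> FeatureVector:
    """HOG descriptor of a square crop (see module docstring for layout)."""
    params = params or HogParams()
    crop = np.asarray(crop)
    if crop.ndim != 2 or crop.shape[0] != crop.shape[1]:
        raise ValueError("crop must be square")
    side = crop.shape[0]
    if side < params.cell * params.block:
        raise ValueError("crop smaller than one block")
    hist = cell_histograms(crop, params)
    nc_y, nc_x, bins = hist.shape
    b, s = params.block, params.block_stride
    win = np.lib.stride_tricks.sliding_window_view(hist, (b, b), axis=(0, 1))
    blocks = win[::s, ::s]  # (nby, nbx, bins, b, b)
    nby, nbx = blocks.shape[:2]
    # within-block order: cells row-major, bins innermost
    blocks = np.ascontiguousarray(blocks.transpose(0, 1, 3, 4, 2)).reshape(
        nby, nbx, b * b * bins
    )
    eps = 1e-10
    norms = np.sqrt((blocks**2).sum(axis=-1, keepdims=True) + eps**2)
    v = blocks / norms
    v = np.minimum(v, params.clip)
    norms2 = np.sqrt((v**2).sum(axis=-1, keepdims=True) + eps**2)
    v = v / norms2
    # zero-gradient blocks stay exactly zero
    zero = (blocks**2).sum(axis=-1, keepdims=True) == 0
    v = np.where(zero, 0.0, v)
    return FeatureVector(
        values=v.ravel(),
        cells=(nc_y, nc_x),
        bins=bins,
        block=b,
        block_stride=s,
    )
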