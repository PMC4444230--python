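"""Independent brute-force oracles shared across test modules."""

import numpy as np


def otsu_exhaustive(image):
    """Independent oracle: scan all 256 thresholds on the raw histogram."""
    flat = image.ravel().astype(float)
    n = flat.size
    best_t, best_s = 0, -1.0
    mu_t = flat.mean()
    for t in range(256):
        fg = flat[flat <= t]
        bg = flat[flat > t]
        w0 = fg.size / n
        w1 = bg.size / n
        s = 0.0
        if fg.size:
            s += w0 * (fg.mean() - mu_t) ** 2
        if bg.size:
            s += w1 * (bg.mean() - mu_t) ** 2
        if s > best_s + 1e-12:
            best_s, best_t = s, t
    return best_t, best_s


def sauvola_naive(image, params):
    """Independent oracle: per-pixel window statistics by direct summation."""
    r = params.window // 2
    pad = np.pad(image.astype(np.int64), r, mode="reflect")
    h, w = image.shape
    n = params.window**2
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            win = pad[i : i + params.window, j : j + params.window]
            m = win.sum() / n
            var = (win * win).sum() / n - m * m
            s = np.sqrt(max(var, 0.0))
            t = m * (1 + params.k * (s / params.R - 1))
            out[i, j] = image[i, j] < t
    return out
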