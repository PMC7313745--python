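"""Brute-force reference implementations used only as test oracles.

Each oracle recomputes an operator's defining mathematics by direct
exhaustive evaluation (explicit footprint scans, threshold-by-threshold
flooding, dense grid search) with no code shared with the package, so a
match is evidence of correctness rather than of common bugs.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def brute_ball_closing(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale closing with a spherical SE by exhaustive max/min scans."""
    r = int(radius)
    dy, dx = np.mgrid[-r: r + 1, -r: r + 1]
    d2 = dy * dy + dx * dx
    inside = d2 <= r * r
    heights = np.sqrt((r * r - d2).clip(0)).astype(np.float64)
    a = np.pad(img.astype(np.float64), r, mode="edge")
    h, w = img.shape
    dil = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            win = a[i: i + 2 * r + 1, j: j + 2 * r + 1]
            dil[i, j] = (win + heights)[inside].max()
    b = np.pad(dil, r, mode="edge")
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            win = b[i: i + 2 * r + 1, j: j + 2 * r + 1]
            out[i, j] = (win - heights)[inside].min()
    return out


def brute_subtract_background_light(img: np.ndarray, radius: int) -> np.ndarray:
    """Light-background rolling-ball subtraction from the brute closing."""
    bg = brute_ball_closing(img, radius)
    out = np.floor(img.astype(np.float64) - bg + 255.0 + 0.5)
    return np.clip(out, 0, 255).astype(np.uint8)


def brute_median_disc(img: np.ndarray, radius: int) -> np.ndarray:
    """Position-by-position median over an enumerated disc footprint."""
    r = int(radius)
    dy, dx = np.mgrid[-r: r + 1, -r: r + 1]
    inside = (dy * dy + dx * dx) <= r * r
    a = np.pad(img, r, mode="edge")
    h, w = img.shape
    out = np.empty((h, w), dtype=img.dtype)
    for i in range(h):
        for j in range(w):
            win = a[i: i + 2 * r + 1, j: j + 2 * r + 1]
            out[i, j] = np.median(win[inside])
    return out


def brute_minima_count(img: np.ndarray, min_prominence: int,
                       mask: np.ndarray | None = None) -> int:
    """Count prominence-filtered regional minima by threshold flooding.

    Labels the sublevel set at every intensity threshold in ascending
    order and tracks connected-component births and merges: a basin dies
    at the first level where it joins a deeper one (prominence = level −
    birth level); basins never absorbed are referenced against the mask
    maximum.  Independent of the package's union-find sweep.
    """
    a = np.asarray(img)
    m = np.ones(a.shape, bool) if mask is None else np.asarray(mask, bool)
    if not m.any():
        return 0
    ref = int(a[m].max())
    struct = np.ones((3, 3), bool)
    # alive basins: representative pixel -> birth level
    alive: dict[tuple[int, int], int] = {}
    n_prominent = 0
    levels = np.unique(a[m & (a < ref) & (a < 255)])
    for t in levels.tolist():
        sub = m & (a <= t) & (a < 255) & (a < ref)
        labels, n = ndimage.label(sub, structure=struct)
        groups: dict[int, list[tuple[int, int]]] = {}
        for rep in alive:
            groups.setdefault(labels[rep], []).append(rep)
        for lab, reps in groups.items():
            if len(reps) < 2:
                continue
            keeper = min(reps, key=lambda p: (alive[p], p))
            for rep in reps:
                if rep == keeper:
                    continue
                if t - alive[rep] >= min_prominence:
                    n_prominent += 1
                del alive[rep]
        claimed = {labels[rep] for rep in alive}
        for lab in range(1, n + 1):
            if lab not in claimed:
                pix = np.argwhere(labels == lab)
                rep = tuple(pix[np.lexsort((pix[:, 1], pix[:, 0]))[0]])
                alive[rep] = t
    for rep, birth in alive.items():
        if ref - birth >= min_prominence:
            n_prominent += 1
    return n_prominent


def grid_search_slope(x, y, cv_x: float, cv_y: float,
                      lo: float = 1e-3, hi: float = 10.0) -> float:
    """Dense 1-D grid search of the effective-variance chi-square.

    Three successive refinements around the best grid point give the
    minimizing slope to well below 1e-4.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def chi2(b):
        b = np.asarray(b)[:, None]
        return (((y - b * x) ** 2
                 / ((b * cv_x * x) ** 2 + (cv_y * y) ** 2))).sum(axis=1)

    for _ in range(4):
        grid = np.linspace(lo, hi, 20_001)
        best = grid[np.argmin(chi2(grid))]
        span = (hi - lo) / 20_000
        lo, hi = best - 10 * span, best + 10 * span
    return float(best)
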