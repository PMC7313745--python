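"""Pixel-level operators of the colony-enumeration pipeline.

All operators work on 2-D ``uint8`` arrays (8-bit grayscale, the pipeline's
sole pixel currency), preserve the input shape, and are fully deterministic.
The processing chain assumes colonies appear *darker* than their local
background and that each colony has a single darkest spot marking its
center; the operators below successively remove smooth background
variation, expand contrast, suppress sensor noise, push the residual
background to pure white, and finally count prominent regional minima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage


class Point(NamedTuple):
    """Pixel coordinate, 0-based, (row, col), at pixel centers."""

    row_px: int
    col_px: int


@dataclass(frozen=True)
class GrayImage:
    """8-bit grayscale raster with a physical pixel pitch.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array of intensities in [0, 255].
    pixel_pitch_um
        Edge length of one pixel in micrometers (default 40 µm, the
        working resolution needed to resolve 0.5 mm colonies).
    """

    pixels: np.ndarray
    pixel_pitch_um: float = 40.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if not (np.issubdtype(px.dtype, np.integer)
                    and px.min() >= 0 and px.max() <= 255):
                raise ValueError("intensities must be integers in [0, 255]")
            px = px.astype(np.uint8)
        if not self.pixel_pitch_um > 0:
            raise ValueError("pixel_pitch_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def pixel_pitch_mm(self) -> float:
        return self.pixel_pitch_um / 1000.0


@dataclass(frozen=True)
class PipelineParams:
    """Operator parameters of the enumeration pipeline.

    The defaults reproduce the reference configuration: rolling-ball
    radius 50 px (4 mm maximum object diameter at 40 µm/px), median
    working radius 6 px (≈0.25 mm, the smallest object kept), brightness
    lift 135, and a 0.35 % per-tail saturation for the automatic contrast
    expansion.  ``min_prominence`` is the noise tolerance of the minima
    detector on the post-contrast intensity scale; it is not fixed by the
    reference procedure and is exposed as a tunable (default 10 gray
    levels, comfortably above residual noise after median filtering).
    ``contrast_min_range`` guards the contrast expansion: when the
    background-subtracted dynamic range inside a region stays below it,
    the region holds no colonies (colony cores are several times deeper)
    and stretching would only amplify residual noise into false minima,
    so the expansion is skipped.
    """

    rolling_ball_radius_px: int = 50
    median_radius_px: int = 6
    brightness_lift: int = 135
    min_prominence: int = 10
    contrast_saturation_fraction: float = 0.0035
    contrast_min_range: int = 32
    light_background: bool = True

    def __post_init__(self) -> None:
        if self.rolling_ball_radius_px < 1:
            raise ValueError("rolling_ball_radius_px must be >= 1")
        if self.median_radius_px < 1:
            raise ValueError("median_radius_px must be >= 1")
        if self.rolling_ball_radius_px <= self.median_radius_px:
            raise ValueError(
                "rolling_ball_radius_px must exceed median_radius_px "
                "(background scale must exceed object scale)")
        if not 0 <= self.brightness_lift <= 255:
            raise ValueError("brightness_lift must be in [0, 255]")
        if self.min_prominence < 1:
            raise ValueError("min_prominence must be >= 1")
        if not 0 <= self.contrast_saturation_fraction < 0.5:
            raise ValueError("contrast_saturation_fraction must be in [0, 0.5)")
        if not 1 <= self.contrast_min_range <= 255:
            raise ValueError("contrast_min_range must be in [1, 255]")


def _as_uint8(img: np.ndarray | GrayImage) -> np.ndarray:
    if isinstance(img, GrayImage):
        return img.pixels
    a = np.asarray(img)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if a.dtype != np.uint8:
        if not (np.issubdtype(a.dtype, np.integer)
                and a.min() >= 0 and a.max() <= 255):
            raise ValueError("image intensities must be integers in [0, 255]")
        a = a.astype(np.uint8)
    return a


def round_half_up(x: np.ndarray | float) -> np.ndarray:
    """Round to nearest integer, halves away from zero toward +inf.

    The single rounding convention used by every linear rescaling in the
    package (NumPy's default rounds halves to even, which would make
    printed ratios like 1.125 -> 1.13 irreproducible).
    """
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


# ---------------------------------------------------------------------------
# rolling-ball background subtraction
# ---------------------------------------------------------------------------

def _ball_dilate(img: np.ndarray, radius: int, erode: bool = False) -> np.ndarray:
    """Grayscale dilation (or erosion) by a spherical structuring element.

    The ball of radius ``r`` is decomposed row-wise: its height profile at
    row offset dy is a 1-D semicircle of radius sqrt(r² − dy²), so the 2-D
    dilation is the max over dy of 1-D semicircle dilations.  Exact (no
    downsampling), borders handled by edge replication.
    """
    r = int(radius)
    f = img.astype(np.float32)
    if erode:
        f = -f
    h, w = f.shape
    pad = np.pad(f, r, mode="edge")
    out = np.full((h, w), -np.inf, dtype=np.float32)
    acc = np.empty((h, w), dtype=np.float32)
    for dy in range(-r, r + 1):
        rho2 = float(r * r - dy * dy)
        mdx = int(np.floor(np.sqrt(rho2)))
        slab = pad[r + dy: r + dy + h]
        acc.fill(-np.inf)
        for dx in range(-mdx, mdx + 1):
            hgt = np.float32(np.sqrt(rho2 - dx * dx))
            np.maximum(acc, slab[:, r + dx: r + dx + w] + hgt, out=acc)
        np.maximum(out, acc, out=out)
    return -out if erode else out


def ball_closing(img: np.ndarray | GrayImage, radius_px: int) -> np.ndarray:
    """Grayscale closing with a spherical structuring element (float output).

    Fills dark features narrower than the ball; the result is a smooth
    upper envelope of the intensity surface — the background estimate for
    a light-background image.
    """
    a = _as_uint8(img)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if radius_px > min(a.shape):
        raise ValueError("radius_px exceeds the image's smaller dimension")
    return _ball_dilate(_ball_dilate(a, radius_px), radius_px, erode=True)


def subtract_background(img: np.ndarray | GrayImage, radius_px: int = 50,
                        light_background: bool = True) -> np.ndarray:
    """Remove smooth background variation with the rolling-ball operator.

    A ball of the given radius is rolled over (light background) or under
    (dark background) the intensity surface; the surface it traces is the
    background estimate and is subtracted.  The radius must exceed the
    radius of the largest object to preserve: features wider than twice
    the radius are treated as background.  With ``light_background`` the
    background maps to pure white (255) and dark objects survive as
    dark-on-white features.
    """
    a = _as_uint8(img)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if radius_px > min(a.shape):
        raise ValueError("radius_px exceeds the image's smaller dimension")
    if light_background:
        bg = _ball_dilate(_ball_dilate(a, radius_px), radius_px, erode=True)
        out = a.astype(np.float32) - bg + 255.0
    else:
        bg = _ball_dilate(_ball_dilate(a, radius_px, erode=True), radius_px)
        out = a.astype(np.float32) - bg
    return np.clip(round_half_up(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# automatic contrast expansion
# ---------------------------------------------------------------------------

def auto_contrast(img: np.ndarray | GrayImage, saturation_fraction: float = 0.0035,
                  stats_mask: np.ndarray | None = None,
                  min_dynamic_range: int = 1) -> np.ndarray:
    """Linearly spread gray values across the full 8-bit dynamic range.

    The lower and upper stretch bounds are the intensities at which the
    cumulative histogram passes ``saturation_fraction`` of the pixels
    from either end; values outside clamp to 0 / 255.  With fraction 0
    the bounds are the exact min and max.  ``stats_mask`` restricts the
    histogram (not the application) to a region of interest, so that
    pixels outside the countable area cannot skew the bounds.

    A degenerate range — bounds closer than ``min_dynamic_range`` —
    returns the image unchanged; a constant image is always degenerate.
    The expansion is only meaningful when every gray value represents
    either remaining background or an object: callers processing
    background-subtracted plates raise ``min_dynamic_range`` so that a
    featureless (colony-free) region, whose residual range is far below
    any real colony depth, is not stretched into spurious structure.
    """
    a = _as_uint8(img)
    if not 0 <= saturation_fraction < 0.5:
        raise ValueError("saturation_fraction must be in [0, 0.5)")
    if min_dynamic_range < 1:
        raise ValueError("min_dynamic_range must be >= 1")
    vals = a[stats_mask] if stats_mask is not None else a.ravel()
    if vals.size == 0:
        raise ValueError("stats_mask selects no pixels")
    counts = np.bincount(vals, minlength=256)
    thresh = saturation_fraction * vals.size
    cum = np.cumsum(counts)
    low = int(np.searchsorted(cum, thresh, side="right"))
    cum_hi = np.cumsum(counts[::-1])
    high = 255 - int(np.searchsorted(cum_hi, thresh, side="right"))
    if high - low < min_dynamic_range:
        return a.copy()
    # integer multiply before the divide keeps exact halves (e.g. 127.5) exact
    scaled = (a.astype(np.int64) - low) * 255.0 / (high - low)
    return np.clip(round_half_up(scaled), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# median filtering
# ---------------------------------------------------------------------------

def disc_footprint(radius_px: int) -> np.ndarray:
    """Boolean disc of the given radius (dx² + dy² ≤ r²); always odd count."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    r = int(radius_px)
    dy, dx = np.mgrid[-r: r + 1, -r: r + 1]
    return (dx * dx + dy * dy) <= r * r


def median_filter(img: np.ndarray | GrayImage, radius_px: int = 6) -> np.ndarray:
    """Median over a disc neighborhood; removes noise and sub-disc objects.

    Each output pixel is the median of the input intensities within a
    disc of ``radius_px`` centered on it (edge replication at borders).
    Isolated features smaller than the disc are eliminated — which also
    intentionally excludes microcolonies below the counting size.
    """
    a = _as_uint8(img)
    return ndimage.median_filter(a, footprint=disc_footprint(radius_px),
                                 mode="nearest")


# ---------------------------------------------------------------------------
# brightness lift
# ---------------------------------------------------------------------------

def lift_brightness(img: np.ndarray | GrayImage, delta: int = 135) -> np.ndarray:
    """Saturating addition: v -> min(v + delta, 255).

    Pushes the residual background, still carrying low-contrast artifacts
    after contrast expansion, above the 8-bit maximum so that only object
    interiors retain grayscale structure.
    """
    a = _as_uint8(img)
    if not 0 <= delta <= 255:
        raise ValueError("delta must be in [0, 255]")
    return np.minimum(a.astype(np.int16) + delta, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# prominence-filtered regional minima
# ---------------------------------------------------------------------------

_NBRS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


def find_local_minima(img: np.ndarray | GrayImage, min_prominence: int = 10,
                      mask: np.ndarray | None = None) -> list[Point]:
    """Detect regional minima whose prominence reaches ``min_prominence``.

    The prominence of a regional minimum is its depth below the lowest
    saddle that connects it (8-connectivity) to a deeper minimum; the
    deepest minimum inside the mask is referenced against the mask's
    background level (its maximum intensity).  One point is returned per
    qualifying minimum; a flat plateau contributes a single point at its
    centroid pixel (ties broken by smallest row, then column).  Pixels at
    exactly 255 are lifted background and are never minima.

    Computed with a union-find sweep over pixels in ascending intensity:
    each regional minimum starts a basin, and when two basins meet the
    shallower one dies at the connecting saddle, fixing its prominence.
    """
    a = _as_uint8(img)
    if min_prominence < 1:
        raise ValueError("min_prominence must be >= 1")
    h, w = a.shape
    if mask is None:
        m = np.ones((h, w), dtype=bool)
    else:
        m = np.asarray(mask)
        if m.shape != a.shape:
            raise ValueError("mask shape must match image shape")
        m = m.astype(bool)
    if not m.any():
        return []
    ref = int(a[m].max())

    sel = m & (a < ref) & (a < 255)
    rows, cols = np.nonzero(sel)
    if rows.size == 0:
        return []
    vals = a[rows, cols].astype(np.int64)
    order = np.lexsort((cols, rows, vals))
    rows, cols, vals = rows[order], cols[order], vals[order]

    idx = np.full((h, w), -1, dtype=np.int64)  # pixel -> component id
    parent: list[int] = []
    comp_min: list[int] = []
    comp_birth: list[tuple[int, int]] = []
    # (birth row, birth col, min value, prominence)
    finished: list[tuple[int, int, int, int]] = []

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    rl, cl, vl = rows.tolist(), cols.tolist(), vals.tolist()
    for k in range(len(rl)):
        r, c, v = rl[k], cl[k], vl[k]
        roots: list[int] = []
        for dr, dc in _NBRS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and idx[rr, cc] >= 0:
                root = find(idx[rr, cc])
                if root not in roots:
                    roots.append(root)
        if not roots:
            cid = len(parent)
            parent.append(cid)
            comp_min.append(v)
            comp_birth.append((r, c))
            idx[r, c] = cid
            continue
        # deepest basin survives; ties resolved by earliest (lowest) birth
        winner = min(roots, key=lambda i: (comp_min[i], comp_birth[i]))
        for root in roots:
            if root == winner:
                continue
            prom = v - comp_min[root]
            if prom >= min_prominence:
                br, bc = comp_birth[root]
                finished.append((br, bc, comp_min[root], prom))
            parent[root] = winner
        idx[r, c] = winner

    seen: set[int] = set()
    for i in range(len(parent)):
        root = find(i)
        if root not in seen:
            seen.add(root)
            prom = ref - comp_min[root]
            if prom >= min_prominence:
                br, bc = comp_birth[root]
                finished.append((br, bc, comp_min[root], prom))

    pts = [_plateau_centroid(a, m, br, bc, mv) for br, bc, mv, _ in finished]
    pts.sort()
    return pts


def _plateau_centroid(a: np.ndarray, mask: np.ndarray,
                      r0: int, c0: int, value: int) -> Point:
    """Centroid pixel of the equal-value plateau containing (r0, c0)."""
    h, w = a.shape
    plateau = [(r0, c0)]
    seen = {(r0, c0)}
    stack = [(r0, c0)]
    while stack:
        r, c = stack.pop()
        for dr, dc in _NBRS:
            rr, cc = r + dr, c + dc
            if (0 <= rr < h and 0 <= cc < w and (rr, cc) not in seen
                    and mask[rr, cc] and a[rr, cc] == value):
                seen.add((rr, cc))
                plateau.append((rr, cc))
                stack.append((rr, cc))
    if len(plateau) == 1:
        return Point(r0, c0)
    pr = np.array([p[0] for p in plateau], dtype=np.float64)
    pc = np.array([p[1] for p in plateau], dtype=np.float64)
    cr, cc_ = pr.mean(), pc.mean()
    d2 = (pr - cr) ** 2 + (pc - cc_) ** 2
    best = min(zip(d2.tolist(), plateau))
    return Point(*best[1])
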