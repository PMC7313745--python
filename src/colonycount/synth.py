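"""Seed-controlled synthetic plate images with exact ground truth.

Emulates backlit grayscale imaging of an agar plate at ≈40 µm/pixel:
a bright background with a smooth low-order brightness gradient (variable
broth-layer thickness), additive sensor noise, and dark circular colonies
0.5–4 mm in diameter whose radial profile darkens smoothly toward a
single darkest spot at the center — the premise the enumeration pipeline
relies on.  Generation is a pure function of the spec (including its
seed), so every image is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .imageproc import GrayImage, Point, round_half_up
from .layout import PlateLayout, Roi, make_rois

_MAX_ATTEMPTS = 10_000  # rejection-sampling bound per colony


@dataclass(frozen=True)
class SyntheticPlateSpec:
    """Recipe for one synthetic plate.

    ``n_colonies`` is either a total (distributed as evenly as possible
    over the layout's regions) or a per-region list.  ``min_separation_mm``
    defaults to twice the maximum colony diameter — the "well separated"
    regime; pass a smaller value to provoke confluence.  Colony center
    darkness is the intensity drop at the colony center relative to the
    local background; because a plate carries a single strain at a single
    incubation age, it is sampled once per plate from ``darkness_range``
    (between-plate variability), with each colony reduced by at most
    ``darkness_jitter`` (relative) around that plate-level value.
    """

    layout: PlateLayout
    n_colonies: int | Sequence[int] = 50
    diameter_range_mm: tuple[float, float] = (0.5, 2.0)
    darkness_range: tuple[float, float] = (60.0, 140.0)
    darkness_jitter: float = 0.08
    profile_exponent: float = 0.5
    background_level: float = 230.0
    background_gradient: float = 15.0
    noise_sigma: float = 3.0
    min_separation_mm: float | None = None
    seed: int = 0
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.diameter_range_mm
        if not 0 < lo <= hi:
            raise ValueError("diameter_range_mm must satisfy 0 < min <= max")
        dlo, dhi = self.darkness_range
        if not 0 < dlo <= dhi <= 255:
            raise ValueError("darkness_range must satisfy 0 < min <= max <= 255")
        if not 0 <= self.darkness_jitter < 1:
            raise ValueError("darkness_jitter must be in [0, 1)")
        if self.profile_exponent <= 0:
            raise ValueError("profile_exponent must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.min_separation_mm is not None and self.min_separation_mm < 0:
            raise ValueError("min_separation_mm must be >= 0")

    @property
    def separation_mm(self) -> float:
        if self.min_separation_mm is not None:
            return self.min_separation_mm
        return 2.0 * self.diameter_range_mm[1]

    def counts_per_roi(self, n_rois: int) -> list[int]:
        if isinstance(self.n_colonies, (int, np.integer)):
            n = int(self.n_colonies)
            if n < 0:
                raise ValueError("n_colonies must be >= 0")
            base, extra = divmod(n, n_rois)
            return [base + (1 if i < extra else 0) for i in range(n_rois)]
        counts = [int(c) for c in self.n_colonies]
        if len(counts) != n_rois or any(c < 0 for c in counts):
            raise ValueError(
                f"n_colonies list must have {n_rois} non-negative entries")
        return counts


@dataclass(frozen=True)
class GroundTruth:
    """Placed colony centers (pixel coordinates) with their ROI labels."""

    centers: list[tuple[str, Point]] = field(default_factory=list)

    @property
    def n_per_roi(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for label, _ in self.centers:
            out[label] = out.get(label, 0) + 1
        return out

    @property
    def total(self) -> int:
        return len(self.centers)


class PackingError(RuntimeError):
    """Colony placement could not satisfy the separation constraint."""


def _default_shape(layout: PlateLayout) -> tuple[int, int]:
    h = int(math.ceil(layout.center_row_px + layout.dish_radius_px)) + 2
    w = int(math.ceil(layout.center_col_px + layout.dish_radius_px)) + 2
    return (h, w)


def _fits_inside(roi: Roi, cy: float, cx: float, r_px: float) -> bool:
    """True if a colony disc of radius r_px lies entirely inside the ROI."""
    dr, dc = cy - roi.center_row_px, cx - roi.center_col_px
    d = math.hypot(dr, dc)
    if d + r_px > roi.radius_px:
        return False
    if roi.wedge_deg is None:
        return True
    if d <= r_px:
        return False  # dish center: no angular clearance possible
    start, end = roi.wedge_deg
    extent = (end - start) % 360.0
    theta = math.degrees(math.atan2(-dr, dc)) % 360.0
    margin = math.degrees(math.asin(min(1.0, r_px / d)))
    span = (theta - start) % 360.0
    return margin <= span <= extent - margin


def _background_field(shape: tuple[int, int], level: float, amplitude: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Bright background with a random low-order polynomial gradient."""
    h, w = shape
    y = np.linspace(-1.0, 1.0, h)[:, None]
    x = np.linspace(-1.0, 1.0, w)[None, :]
    coef = rng.uniform(-1.0, 1.0, size=5)
    poly = (coef[0] * x + coef[1] * y + coef[2] * x * y
            + coef[3] * x * x + coef[4] * y * y)
    peak = np.abs(poly).max()
    if peak > 0 and amplitude > 0:
        poly = poly * (amplitude / peak)
    else:
        poly = np.zeros_like(poly)
    return level + poly


def _render_colony(darkness: np.ndarray, cy: float, cx: float,
                   r_px: float, depth: float, exponent: float = 0.5) -> None:
    """Accumulate a radial darkness profile: depth·(1 − (d/r)²)^exponent.

    Smooth, monotone darkening toward a single darkest spot.  The default
    exponent 0.5 is a hemispherical dome: its rendered footprint spans
    the full nominal diameter (the profile only falls below one gray
    level within a fraction of a pixel of the edge), matching how opaque
    a backlit colony looks out to its physical rim.

    Where colonies touch, darkness composes as the pointwise *maximum*:
    colonies are opaque bodies that abut rather than transparent films
    that stack, so each keeps its own darkest center and confluent
    neighbors are separated by a brighter seam — the property that lets
    clustered colonies be counted as multiple distinct minima.
    """
    h, w = darkness.shape
    r0, r1 = max(0, int(cy - r_px) - 1), min(h, int(cy + r_px) + 2)
    c0, c1 = max(0, int(cx - r_px) - 1), min(w, int(cx + r_px) + 2)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (r_px * r_px)
    prof = depth * np.clip(1.0 - d2, 0.0, None) ** exponent
    np.maximum(darkness[r0:r1, c0:c1], prof, out=darkness[r0:r1, c0:c1])


def _place_colonies(spec: SyntheticPlateSpec, rois: list[Roi],
                    rng: np.random.Generator):
    """Uniform rejection sampling of centers honoring the separation rule."""
    pitch_px = spec.layout.pixel_pitch_um / 1000.0  # mm per pixel
    sep_px = spec.separation_mm / pitch_px
    counts = spec.counts_per_roi(len(rois))
    # one strain at one incubation age per plate: center darkness is a
    # plate-level property; colonies deviate from it only slightly
    base_depth = rng.uniform(*spec.darkness_range)
    placed: list[tuple[str, float, float, float, float]] = []
    ys: list[float] = []
    xs: list[float] = []
    for roi, n in zip(rois, counts):
        for _ in range(n):
            for _attempt in range(_MAX_ATTEMPTS):
                ang = rng.uniform(0.0, 2.0 * math.pi)
                rad = roi.radius_px * math.sqrt(rng.uniform())
                cy = roi.center_row_px + rad * math.sin(ang)
                cx = roi.center_col_px + rad * math.cos(ang)
                dia_mm = rng.uniform(*spec.diameter_range_mm)
                depth = base_depth * rng.uniform(1.0 - spec.darkness_jitter, 1.0)
                r_px = 0.5 * dia_mm / pitch_px
                if not _fits_inside(roi, cy, cx, r_px):
                    continue
                if ys:
                    dy = np.asarray(ys) - cy
                    dx = np.asarray(xs) - cx
                    if (dy * dy + dx * dx).min() < sep_px * sep_px:
                        continue
                placed.append((roi.label, cy, cx, r_px, depth))
                ys.append(cy)
                xs.append(cx)
                break
            else:
                raise PackingError(
                    f"could not place colony in {roi.label!r} after "
                    f"{_MAX_ATTEMPTS} attempts (separation "
                    f"{spec.separation_mm} mm too tight for {n} colonies)")
    return placed


def generate_plate(spec: SyntheticPlateSpec) -> tuple[GrayImage, GroundTruth]:
    """Render a synthetic plate and its exact ground truth.

    The image is ``clip(background + gradient − Σ colony profiles +
    noise)`` quantized to 8 bits.  Raises :class:`PackingError` (never
    silently truncates) if the separation constraint cannot be met.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape or _default_shape(spec.layout)
    rois = make_rois(spec.layout)
    placed = _place_colonies(spec, rois, rng)
    canvas = _background_field(shape, spec.background_level,
                               spec.background_gradient, rng)
    darkness = np.zeros(shape, dtype=np.float64)
    for _, cy, cx, r_px, depth in placed:
        _render_colony(darkness, cy, cx, r_px, depth, spec.profile_exponent)
    canvas -= darkness
    if spec.noise_sigma > 0:
        canvas += rng.normal(0.0, spec.noise_sigma, size=shape)
    img = np.clip(round_half_up(canvas), 0, 255).astype(np.uint8)
    truth = GroundTruth([(label, Point(int(round(cy)), int(round(cx))))
                         for label, cy, cx, _, _ in placed])
    return GrayImage(img, spec.layout.pixel_pitch_um), truth


def generate_confluent_pair(spec: SyntheticPlateSpec,
                            overlap_fraction: float
                            ) -> tuple[GrayImage, GroundTruth]:
    """Render exactly two colonies at a controlled degree of overlap.

    Their center distance is ``(1 − overlap_fraction) · (r1 + r2)``; at 0
    they are tangent-disjoint, and as the fraction approaches 1 the pair
    merges into a single dark region (used to characterize the detection
    limit for clustered colonies).
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape or _default_shape(spec.layout)
    layout = spec.layout
    pitch_px = layout.pixel_pitch_um / 1000.0
    # two equal colonies at the mean diameter of the configured range
    r1 = r2 = 0.25 * sum(spec.diameter_range_mm) / pitch_px
    dist = (1.0 - overlap_fraction) * (r1 + r2)
    cy = layout.center_row_px
    cx1 = layout.center_col_px - dist / 2.0
    cx2 = layout.center_col_px + dist / 2.0
    depth1, depth2 = (float(np.mean(spec.darkness_range)),) * 2
    canvas = _background_field(shape, spec.background_level,
                               spec.background_gradient, rng)
    darkness = np.zeros(shape, dtype=np.float64)
    _render_colony(darkness, cy, cx1, r1, depth1, spec.profile_exponent)
    _render_colony(darkness, cy, cx2, r2, depth2, spec.profile_exponent)
    canvas -= darkness
    if spec.noise_sigma > 0:
        canvas += rng.normal(0.0, spec.noise_sigma, size=shape)
    img = np.clip(round_half_up(canvas), 0, 255).astype(np.uint8)
    label = make_rois(layout)[0].label
    truth = GroundTruth([(label, Point(int(round(cy)), int(round(cx1)))),
                         (label, Point(int(round(cy)), int(round(cx2))))])
    return GrayImage(img, layout.pixel_pitch_um), truth
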