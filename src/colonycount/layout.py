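"""Geometry of countable plate regions.

A Petri dish is enumerated either over one full disc or over six wedge
segments (each inoculated with a different dilution of the sample).  The
countable regions stop a few millimeters short of the dish rim, which
avoids both rim colony clusters and the thicker broth layer near the
edge.  Dish position is assumed fixed by a jig, so regions of interest
are defined once per layout rather than detected from the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

_LAYOUT_KEYS = ("center_row_px", "center_col_px", "dish_radius_px",
                "n_segments", "rim_inset_mm", "segment_gap_deg",
                "rotation_deg", "pixel_pitch_um")


@dataclass(frozen=True)
class PlateLayout:
    """Dish position and segmentation scheme, in pixel coordinates.

    ``rim_inset_mm`` shrinks the countable disc radius; the default 3 mm
    keeps clear of rim clusters.  ``segment_gap_deg`` leaves a small
    angular strip between adjacent wedges, mirroring the colony-free
    border lines drawn on segmented dishes, so no colony straddling a
    border is counted twice.  ``rotation_deg`` orients the first segment
    boundary; segments are labeled counter-clockwise from it.
    """

    center_row_px: float
    center_col_px: float
    dish_radius_px: float
    n_segments: int = 1
    rim_inset_mm: float = 3.0
    segment_gap_deg: float = 4.0
    rotation_deg: float = 0.0
    pixel_pitch_um: float = 40.0

    def __post_init__(self) -> None:
        if self.dish_radius_px <= 0:
            raise ValueError("dish_radius_px must be positive")
        if self.n_segments not in (1, 6):
            raise ValueError("n_segments must be 1 or 6")
        if self.rim_inset_mm < 0:
            raise ValueError("rim_inset_mm must be >= 0")
        if self.segment_gap_deg < 0:
            raise ValueError("segment_gap_deg must be >= 0")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.roi_radius_px <= 0:
            raise ValueError("rim inset leaves no countable area "
                             "(inset >= dish radius)")

    @property
    def rim_inset_px(self) -> float:
        return self.rim_inset_mm * 1000.0 / self.pixel_pitch_um

    @property
    def roi_radius_px(self) -> float:
        """Effective countable radius: dish radius minus the rim inset."""
        return self.dish_radius_px - self.rim_inset_px


@dataclass(frozen=True)
class Roi:
    """A countable region: a disc, optionally cut to an angular wedge.

    Membership is a pure function of the geometry.  ``wedge_deg`` is the
    half-open angular interval [start, end) measured counter-clockwise
    (as seen on screen) from the +col axis; ``None`` means the full disc.
    """

    label: str
    center_row_px: float
    center_col_px: float
    radius_px: float
    wedge_deg: tuple[float, float] | None = None
    _mask_cache: dict = field(default_factory=dict, compare=False, repr=False)

    def contains(self, row_px, col_px) -> np.ndarray:
        """Vectorized membership test for pixel-center coordinates."""
        dr = np.asarray(row_px, dtype=np.float64) - self.center_row_px
        dc = np.asarray(col_px, dtype=np.float64) - self.center_col_px
        inside = dr * dr + dc * dc <= self.radius_px ** 2
        if self.wedge_deg is not None:
            start, end = self.wedge_deg
            # image rows grow downward, so negate dr for on-screen CCW angles
            theta = np.degrees(np.arctan2(-dr, dc)) % 360.0
            span = (theta - start) % 360.0
            inside &= span < (end - start) % 360.0
        return inside

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean membership mask, rasterized once per image shape."""
        key = tuple(shape)
        if key not in self._mask_cache:
            rows, cols = np.mgrid[: shape[0], : shape[1]]
            self._mask_cache[key] = self.contains(rows, cols)
        return self._mask_cache[key]


def make_full_plate_roi(layout: PlateLayout) -> Roi:
    """Disc ROI covering the whole countable (inset) plate area."""
    return Roi("full_plate", layout.center_row_px, layout.center_col_px,
               layout.roi_radius_px)


def make_segment_rois(layout: PlateLayout) -> list[Roi]:
    """Six disjoint wedge ROIs of equal angular extent (60° − gap).

    Labeled ``segment_1`` … ``segment_6`` counter-clockwise from
    ``rotation_deg``; the gap is split evenly on both sides of every
    boundary so the wedges never touch.
    """
    if layout.n_segments != 6:
        raise ValueError("segment ROIs require a layout with n_segments=6")
    if layout.segment_gap_deg >= 60.0:
        raise ValueError("segment_gap_deg must be < 60")
    half_gap = layout.segment_gap_deg / 2.0
    rois = []
    for k in range(6):
        start = (layout.rotation_deg + 60.0 * k + half_gap) % 360.0
        end = (layout.rotation_deg + 60.0 * (k + 1) - half_gap) % 360.0
        rois.append(Roi(f"segment_{k + 1}", layout.center_row_px,
                        layout.center_col_px, layout.roi_radius_px,
                        wedge_deg=(start, end)))
    return rois


def make_rois(layout: PlateLayout) -> list[Roi]:
    """The layout's countable regions: one disc or six wedges."""
    if layout.n_segments == 6:
        return make_segment_rois(layout)
    return [make_full_plate_roi(layout)]


def scale_segment_count(count: int, n_segments: int) -> int:
    """Scale a per-region count to its full-plate equivalent.

    A count from a 1/6-plate segment is multiplied by 6 to be comparable
    with enumeration of complete plates; full-plate counts pass through.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if n_segments not in (1, 6):
        raise ValueError("n_segments must be 1 or 6")
    return int(count) * int(n_segments)


def load_layout(path: str | Path) -> PlateLayout:
    """Read a :class:`PlateLayout` from a YAML (or JSON) config file.

    Keys mirror the PlateLayout fields; unknown keys are rejected so a
    typo cannot silently fall back to a default.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"layout config {path} must be a mapping")
    unknown = set(data) - set(_LAYOUT_KEYS)
    if unknown:
        raise ValueError(f"unknown layout key(s): {sorted(unknown)}")
    missing = {"center_row_px", "center_col_px", "dish_radius_px"} - set(data)
    if missing:
        raise ValueError(f"layout config missing key(s): {sorted(missing)}")
    return PlateLayout(**data)
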