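"""Per-region orchestration of the enumeration pipeline.

Applies the five-stage sequence — rolling-ball background subtraction,
automatic contrast expansion, median filtering, brightness lift, and
prominence-filtered minima detection — to each countable region of a
plate, and assembles counts, detected centers, and annotated result
images.  Repeated runs on identical input are bit-identical: every
parameter is predefined, nothing is estimated stochastically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._font import render_text
from .imageproc import (GrayImage, PipelineParams, Point, _as_uint8,
                        auto_contrast, find_local_minima, lift_brightness,
                        median_filter, subtract_background)
from .layout import PlateLayout, Roi, make_rois, scale_segment_count


@dataclass(frozen=True)
class RoiCount:
    """Enumeration result for one countable region."""

    label: str
    count: int
    centers: list[Point]
    full_plate_equivalent: int
    anchor: Point  # region centroid, used to place the rendered count

    def __post_init__(self) -> None:
        if self.count != len(self.centers):
            raise ValueError("count must equal the number of centers")


@dataclass(frozen=True)
class CountResult:
    """Counts and detected centers for a whole plate.

    ``full_plate_equivalent`` scales segment counts by the number of
    segments so results from 1/6-plate regions are comparable with whole
    plates.  ``processed_image`` is the post-pipeline image (composed
    region by region for segmented plates; pure white outside the ROIs)
    in which the detected minima live.
    """

    per_roi: list[RoiCount]
    total_count: int
    full_plate_equivalent: int
    processed_image: GrayImage
    params_used: PipelineParams = field(default_factory=PipelineParams)


def run_pipeline(img: np.ndarray | GrayImage, roi: Roi,
                 params: PipelineParams = PipelineParams(),
                 _background_subtracted: np.ndarray | None = None
                 ) -> tuple[np.ndarray, list[Point]]:
    """Run the five processing stages for a single region of interest.

    The pixel operators run on the full frame; only the contrast-stretch
    statistics are restricted to ROI pixels, so marks or text outside the
    countable area cannot skew the dynamic range.  Returns the processed
    image and the detected colony centers (all inside the ROI).
    """
    a = _as_uint8(img)
    mask = roi.mask(a.shape)
    if _background_subtracted is None:
        _background_subtracted = subtract_background(
            a, params.rolling_ball_radius_px, params.light_background)
    if not mask.any():
        return _background_subtracted.copy(), []
    out = auto_contrast(_background_subtracted,
                        params.contrast_saturation_fraction, stats_mask=mask,
                        min_dynamic_range=params.contrast_min_range)
    out = median_filter(out, params.median_radius_px)
    out = lift_brightness(out, params.brightness_lift)
    centers = find_local_minima(out, params.min_prominence, mask)
    return out, centers


def enumerate_plate(img: np.ndarray | GrayImage, layout: PlateLayout,
                    params: PipelineParams = PipelineParams()) -> CountResult:
    """Enumerate a plate: run the pipeline per region and collect counts.

    The background subtraction (the only region-independent stage that
    dominates runtime) is computed once and shared across regions.
    """
    a = _as_uint8(img)
    if layout.center_row_px >= a.shape[0] or layout.center_col_px >= a.shape[1]:
        raise ValueError("plate layout lies outside the image frame")
    rois = make_rois(layout)
    bg_sub = subtract_background(a, params.rolling_ball_radius_px,
                                 params.light_background)
    composed = np.full(a.shape, 255, dtype=np.uint8)
    per_roi: list[RoiCount] = []
    for roi in rois:
        mask = roi.mask(a.shape)
        processed, centers = run_pipeline(a, roi, params,
                                          _background_subtracted=bg_sub)
        composed[mask] = processed[mask]
        rr, cc = np.nonzero(mask)
        anchor = (Point(int(round(rr.mean())), int(round(cc.mean())))
                  if rr.size else Point(0, 0))
        per_roi.append(RoiCount(
            label=roi.label, count=len(centers), centers=centers,
            full_plate_equivalent=scale_segment_count(len(centers),
                                                      layout.n_segments),
            anchor=anchor))
    total = sum(r.count for r in per_roi)
    pitch = img.pixel_pitch_um if isinstance(img, GrayImage) else 40.0
    return CountResult(
        per_roi=per_roi, total_count=total,
        full_plate_equivalent=scale_segment_count(total, layout.n_segments),
        processed_image=GrayImage(composed, pitch), params_used=params)


def annotate(original: np.ndarray | GrayImage, result: CountResult,
             dilation_steps: int = 1, text_scale: int = 2) -> np.ndarray:
    """Mark detected centers and counts on a copy of the original image.

    Each center becomes a white spot grown by ``dilation_steps`` 3x3
    dilations (a point mark alone is hard to see), and each region's
    numeric count is rendered near the region with the built-in bitmap
    font.  Intended for visual verification against the original.
    """
    if dilation_steps not in (0, 1, 2):
        raise ValueError("dilation_steps must be 0, 1 or 2")
    a = _as_uint8(original).copy()
    if result.per_roi:
        spots = np.zeros(a.shape, dtype=bool)
        for rc in result.per_roi:
            for p in rc.centers:
                spots[p.row_px, p.col_px] = True
        if dilation_steps:
            spots = ndimage.binary_dilation(
                spots, structure=np.ones((3, 3), bool),
                iterations=dilation_steps)
        a[spots] = 255
        for rc in result.per_roi:
            render_text(a, str(rc.count), rc.anchor.row_px, rc.anchor.col_px,
                        value=255, scale=text_scale)
    return a
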