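"""Shared fixtures: small plates sized so the whole suite stays fast."""

from __future__ import annotations

import numpy as np
import pytest

from colonycount import PlateLayout, SyntheticPlateSpec, generate_plate


@pytest.fixture(scope="session")
def small_layout() -> PlateLayout:
    """Scaled-down single-region dish: countable radius 235 px (~9.4 mm)."""
    return PlateLayout(center_row_px=320, center_col_px=320,
                       dish_radius_px=310, n_segments=1)


@pytest.fixture(scope="session")
def small_plate(small_layout):
    """A 10-colony plate with its ground truth (default parameters)."""
    spec = SyntheticPlateSpec(layout=small_layout, n_colonies=10, seed=202)
    return generate_plate(spec)


def blob_image(shape, blobs, background=255):
    """Dark radial blobs on a constant background (uint8).

    ``blobs`` is a list of (row, col, radius, center_value); intensity
    ramps linearly from center_value at the center to background at the
    blob edge, so each blob has a unique darkest pixel.
    """
    img = np.full(shape, background, dtype=float)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for (cy, cx, r, val) in blobs:
        d = np.hypot(yy - cy, xx - cx)
        ramp = val + (background - val) * np.clip(d / r, 0.0, 1.0)
        img = np.minimum(img, ramp)
    return np.round(img).astype(np.uint8)
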