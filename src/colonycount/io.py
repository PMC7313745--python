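"""Image and result-file I/O for the command-line tools.

The pipeline operates on 8-bit grayscale frames.  16-bit grayscale input
is accepted and linearly rescaled to 8 bits with a warning (8-bit
processing was found equivalent for this task); color input is rejected
with guidance, since counting relies on a grayscale intensity surface.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .imageproc import GrayImage, PipelineParams, round_half_up

log = logging.getLogger("colonycount")


def read_image(path: str | Path, pixel_pitch_um: float = 40.0) -> GrayImage:
    """Read an 8-bit grayscale TIFF/PNG (16-bit rescaled with a warning)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        if arr.shape[-1] == 1:
            arr = arr[..., 0]
        else:
            raise ValueError(
                f"{path}: color images are not supported; record or convert "
                "to single-channel grayscale before counting")
    if arr.dtype == np.uint16:
        log.warning("%s: 16-bit input rescaled to 8-bit", path)
        arr = np.clip(round_half_up(arr / 257.0), 0, 255).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}; expected "
                         "8-bit (or 16-bit) grayscale")
    return GrayImage(arr, pixel_pitch_um)


def write_image(path: str | Path, img: np.ndarray | GrayImage) -> None:
    """Write an 8-bit grayscale PNG/TIFF."""
    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    iio.imwrite(Path(path), arr.astype(np.uint8))


def params_hash(params: PipelineParams) -> str:
    """Short stable digest of a parameter set, for result provenance."""
    return hashlib.sha256(repr(params).encode()).hexdigest()[:12]
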