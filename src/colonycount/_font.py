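"""Built-in 5x7 bitmap glyphs for annotating result images.

A fixed bitmap font keeps annotated output bit-reproducible across
platforms (no dependence on system font rendering).  Only the characters
needed for counts are provided.
"""

from __future__ import annotations

import numpy as np

_GLYPHS = {
    "0": ("01110", "10001", "10011", "10101", "11001", "10001", "01110"),
    "1": ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),
    "2": ("01110", "10001", "00001", "00010", "00100", "01000", "11111"),
    "3": ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),
    "4": ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),
    "5": ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),
    "6": ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),
    "7": ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),
    "8": ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),
    "9": ("01110", "10001", "10001", "01111", "00001", "00010", "01100"),
    " ": ("00000", "00000", "00000", "00000", "00000", "00000", "00000"),
}


def render_text(canvas: np.ndarray, text: str, row: int, col: int,
                value: int = 255, scale: int = 2) -> None:
    """Draw ``text`` onto ``canvas`` in place, top-left corner at (row, col).

    Unknown characters are skipped; glyphs falling outside the canvas are
    clipped.  ``scale`` magnifies the 5x7 base glyphs.
    """
    h, w = canvas.shape
    x = col
    for ch in text:
        glyph = _GLYPHS.get(ch)
        if glyph is None:
            continue
        for gr, line in enumerate(glyph):
            for gc, bit in enumerate(line):
                if bit != "1":
                    continue
                r0, c0 = row + gr * scale, x + gc * scale
                r1, c1 = min(r0 + scale, h), min(c0 + scale, w)
                if r0 < h and c0 < w and r1 > max(r0, 0) and c1 > max(c0, 0):
                    canvas[max(r0, 0):r1, max(c0, 0):c1] = value
        x += (5 + 1) * scale  # glyph width plus one-column spacing
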