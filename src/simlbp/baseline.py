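"""Classic 3x3 local binary pattern baseline.

The canonical LBP: each of the 8 perimeter neighbours, walked clockwise
from the top-left cell, yields bit 1 iff neighbour >= centre; the bits are
weighted exactly as in the SIM-LBP code so outputs are comparable
cell-for-cell.  Invariant under any strictly increasing remapping of the
whole image's intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transform import (
    BIT_ORDERS,
    CLOCKWISE_PERIMETER,
    PADDING_MODES,
    ConfigError,
    PixelWindow3x3,
    _output_geometry,
    as_gray_image,
    extract_window,
    weighted_pixel_value,
)

__all__ = ["LbpConfig", "classic_lbp_pixel", "classic_lbp_transform",
           "classic_lbp_transform_naive"]


@dataclass(frozen=True)
class LbpConfig:
    """Shared conventions (the tie rule neighbour >= centre -> 1 is fixed)."""

    bit_order: str = "lsb_at_top_left"
    padding: str = "replicate"

    def __post_init__(self) -> None:
        if self.bit_order not in BIT_ORDERS:
            raise ConfigError(f"unknown bit_order {self.bit_order!r}")
        if self.padding not in PADDING_MODES:
            raise ConfigError(f"unknown padding {self.padding!r}")


def classic_lbp_pixel(window: PixelWindow3x3, config: LbpConfig = LbpConfig()) -> int:
    a = window.as_array()
    center = a[1, 1]
    bits = [int(a[r, c] >= center) for r, c in CLOCKWISE_PERIMETER]
    return weighted_pixel_value(bits, config.bit_order)


def classic_lbp_transform(image, config: LbpConfig = LbpConfig()) -> np.ndarray:
    """Vectorised classic LBP over the whole image (fresh output buffer)."""
    img = as_gray_image(image)
    P, oh, ow = _output_geometry(img, config.padding)
    center = P[1 : 1 + oh, 1 : 1 + ow]
    if config.bit_order == "lsb_at_top_left":
        weights = [1 << i for i in range(8)]
    else:
        weights = [1 << (7 - i) for i in range(8)]
    out = np.zeros((oh, ow), dtype=np.int64)
    for (r, c), wgt in zip(CLOCKWISE_PERIMETER, weights):
        out += (P[r : r + oh, c : c + ow] >= center).astype(np.int64) * wgt
    return out.astype(np.uint8)


def classic_lbp_transform_naive(image, config: LbpConfig = LbpConfig()) -> np.ndarray:
    """Per-pixel reference loop (oracle for the vectorised path)."""
    img = as_gray_image(image)
    h, w = img.shape
    if config.padding == "crop":
        if h < 3 or w < 3:
            raise ValueError("crop padding needs an image of at least 3x3")
        rows, cols = range(1, h - 1), range(1, w - 1)
    else:
        rows, cols = range(h), range(w)
    out = np.empty((len(rows), len(cols)), dtype=np.uint8)
    for oi, r in enumerate(rows):
        for oj, c in enumerate(cols):
            out[oi, oj] = classic_lbp_pixel(extract_window(img, r, c, config.padding), config)
    return out
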