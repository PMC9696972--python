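"""Symmetric inline matrix LBP (SIM-LBP) per-pixel transform.

The descriptor encodes each pixel of an 8-bit grayscale image from its 3x3
neighbourhood.  The nine window intensities are labelled by column:

    SL1 SC1 SR1
    SL2 SC2 SR2
    SL3 SC3 SR3

Six signed comparison pairs are formed — one per centre-column pixel (its
left and right neighbours minus itself) and one per middle-row pixel (its
upper and lower neighbours minus itself).  Each pair is thresholded against
a feature-coefficient value derived from the pair's mean and variance,
producing six bit pairs.  The vertical bit pairs are split symmetrically
into the left/right cells of a 3x3 binary matrix, the horizontal pairs into
the top/bottom cells of a second matrix; the two matrices are OR-merged,
the 8 perimeter bits are read clockwise from the top-left cell, and the
resulting byte (the weighted pixel value) becomes the output intensity.

Two code paths are provided: :func:`sim_lbp_transform` (vectorised, the one
to use) and :func:`sim_lbp_transform_naive`, a literal per-pixel composition
of the stage functions kept as the reference oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SIGN_CONVENTIONS",
    "COEFFICIENT_MODES",
    "BIT_ORDERS",
    "PADDING_MODES",
    "TransformConfig",
    "PixelWindow3x3",
    "ComparisonPairSet",
    "FeatureCoefficients",
    "BinaryPairSet",
    "SplitMatrices",
    "extract_window",
    "compute_comparison_pairs",
    "compute_feature_coefficients",
    "binarize_pairs",
    "symmetric_split",
    "flatten_clockwise",
    "weighted_pixel_value",
    "sim_lbp_pixel",
    "sim_lbp_transform",
    "sim_lbp_transform_naive",
    "as_gray_image",
]

SIGN_CONVENTIONS = ("neighbor_minus_center", "center_minus_neighbor")
COEFFICIENT_MODES = ("pair_mean_over_variance", "global_sum", "center_pixel")
BIT_ORDERS = ("lsb_at_top_left", "msb_at_top_left")
PADDING_MODES = ("replicate", "reflect", "zero", "crop")

# clockwise perimeter walk of a 3x3 grid starting at the top-left cell:
# TL, TC, TR, MR, BR, BC, BL, ML
CLOCKWISE_PERIMETER = (
    (0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0),
)

_NP_PAD_MODE = {"replicate": "edge", "reflect": "reflect", "zero": "constant"}


class ConfigError(ValueError):
    """An enumeration field of a config holds an unknown value."""


@dataclass(frozen=True)
class TransformConfig:
    """Conventions resolving the transform's underdetermined choices.

    Parameters
    ----------
    sign_convention
        ``neighbor_minus_center`` (default) computes each comparison as
        neighbour minus anchor; ``center_minus_neighbor`` negates every
        difference.
    coefficient_mode
        ``pair_mean_over_variance`` (default): per-pair threshold
        mean(x,y)/popvar(x,y).  ``global_sum``: the six per-pair terms are
        summed into one shared threshold.  ``center_pixel``: the thresholds
        are the raw anchor intensities SC1,SC2,SC3,SL2,SC2,SR2.
    zero_variance_fallback
        Coefficient used for a pair whose two elements are equal (variance
        zero makes the ratio undefined).  Default 0.0: a flat region then
        binarises to all ones through the tie rule.
    bit_order
        ``lsb_at_top_left`` (default): the first flattened bit has weight
        2**0; ``msb_at_top_left``: weight 2**7.
    padding
        Border handling: ``replicate`` (default), ``reflect``, ``zero`` keep
        the output the size of the input; ``crop`` drops the 1-pixel border.
    """

    sign_convention: str = "neighbor_minus_center"
    coefficient_mode: str = "pair_mean_over_variance"
    zero_variance_fallback: float = 0.0
    bit_order: str = "lsb_at_top_left"
    padding: str = "replicate"

    def __post_init__(self) -> None:
        if self.sign_convention not in SIGN_CONVENTIONS:
            raise ConfigError(f"unknown sign_convention {self.sign_convention!r}")
        if self.coefficient_mode not in COEFFICIENT_MODES:
            raise ConfigError(f"unknown coefficient_mode {self.coefficient_mode!r}")
        if self.bit_order not in BIT_ORDERS:
            raise ConfigError(f"unknown bit_order {self.bit_order!r}")
        if self.padding not in PADDING_MODES:
            raise ConfigError(f"unknown padding {self.padding!r}")
        if not np.isfinite(self.zero_variance_fallback):
            raise ConfigError("zero_variance_fallback must be finite")


@dataclass(frozen=True)
class PixelWindow3x3:
    """The nine intensities of a 3x3 window, labelled by column.

    ``SL``, ``SC``, ``SR`` are the left, centre and right columns, each
    ordered top to bottom (SL1 is the top-left pixel, SL2 below it, ...).
    """

    SL: tuple[float, float, float]
    SC: tuple[float, float, float]
    SR: tuple[float, float, float]

    def __post_init__(self) -> None:
        for col in (self.SL, self.SC, self.SR):
            if len(col) != 3:
                raise ValueError("each window column needs exactly 3 values")
            for v in col:
                if not 0 <= v <= 255:
                    raise ValueError(f"intensity {v} outside [0, 255]")

    @classmethod
    def from_array(cls, a: np.ndarray) -> "PixelWindow3x3":
        a = np.asarray(a, dtype=float)
        if a.shape != (3, 3):
            raise ValueError(f"expected a 3x3 array, got shape {a.shape}")
        return cls(SL=tuple(a[:, 0]), SC=tuple(a[:, 1]), SR=tuple(a[:, 2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.SL, self.SC, self.SR], dtype=float).T


@dataclass(frozen=True)
class ComparisonPairSet:
    """Six ordered signed-difference pairs.

    ``vpairs[i]`` anchors at SC(i+1): (from the LEFT neighbour, from the
    RIGHT neighbour).  ``hpairs[j]`` anchors at the middle-row pixel of
    column j (SL2, SC2, SR2): (from ABOVE, from BELOW).
    """

    vpairs: tuple[tuple[float, float], ...]
    hpairs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vpairs) != 3 or len(self.hpairs) != 3:
            raise ValueError("need exactly 3 vertical and 3 horizontal pairs")

    @property
    def ordered(self) -> tuple[tuple[float, float], ...]:
        """Pairs in canonical order (V1, V2, V3, H1, H2, H3)."""
        return self.vpairs + self.hpairs


@dataclass(frozen=True)
class FeatureCoefficients:
    """Per-pair thresholds (V1,V2,V3,H1,H2,H3) and the variances behind them."""

    fcv: tuple[float, float, float, float, float, float]
    sigma2: tuple[float, float, float, float, float, float]

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigma2):
            raise ValueError("variances must be >= 0")
        if not all(np.isfinite(self.fcv)):
            raise ValueError("coefficients must be finite")


@dataclass(frozen=True)
class BinaryPairSet:
    """Bit pairs, one per comparison pair; every element is 0 or 1."""

    vbp: tuple[tuple[int, int], ...]
    hbp: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for pair in self.vbp + self.hbp:
            if any(b not in (0, 1) for b in pair):
                raise ValueError("bits must be 0 or 1")


@dataclass(frozen=True)
class SplitMatrices:
    """The two symmetric binary splits and their OR merge (3x3 bit grids)."""

    vertical: np.ndarray
    horizontal: np.ndarray
    merged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.merged is None:
            object.__setattr__(
                self, "merged", np.logical_or(self.vertical, self.horizontal).astype(np.uint8)
            )


def as_gray_image(values) -> np.ndarray:
    """Validate and return a 2-D uint8 intensity grid."""
    a = np.asarray(values)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    if a.dtype != np.uint8:
        if np.any(a < 0) or np.any(a > 255):
            raise ValueError("intensities must lie in [0, 255]")
        a = a.astype(np.uint8)
    return a


# ---------------------------------------------------------------------------
# per-pixel stage functions (also the building blocks of the naive oracle)
# ---------------------------------------------------------------------------

def extract_window(image, row: int, col: int, padding: str = "replicate") -> PixelWindow3x3:
    """3x3 window centred at (row, col); off-image cells filled per *padding*."""
    img = as_gray_image(image)
    h, w = img.shape
    if not (0 <= row < h and 0 <= col < w):
        raise IndexError(f"({row}, {col}) outside a {h}x{w} image")
    if padding not in PADDING_MODES:
        raise ConfigError(f"unknown padding {padding!r}")
    if padding == "crop":
        if row == 0 or col == 0 or row == h - 1 or col == w - 1:
            raise IndexError("crop padding: border pixels have no full window")
        return PixelWindow3x3.from_array(img[row - 1 : row + 2, col - 1 : col + 2])
    padded = np.pad(img.astype(float), 1, mode=_NP_PAD_MODE[padding])
    return PixelWindow3x3.from_array(padded[row : row + 3, col : col + 3])


def compute_comparison_pairs(
    window: PixelWindow3x3, sign_convention: str = "neighbor_minus_center"
) -> ComparisonPairSet:
    """The six signed difference pairs of the window.

    Vertical pair i: (SL_i - SC_i, SR_i - SC_i); horizontal pair for column
    X in (L, C, R): (SX1 - SX2, SX3 - SX2).  ``center_minus_neighbor``
    negates every element.
    """
    if sign_convention not in SIGN_CONVENTIONS:
        raise ConfigError(f"unknown sign_convention {sign_convention!r}")
    s = 1.0 if sign_convention == "neighbor_minus_center" else -1.0
    SL, SC, SR = window.SL, window.SC, window.SR
    vpairs = tuple((s * (SL[i] - SC[i]), s * (SR[i] - SC[i])) for i in range(3))
    hpairs = tuple((s * (col[0] - col[1]), s * (col[2] - col[1])) for col in (SL, SC, SR))
    return ComparisonPairSet(vpairs=vpairs, hpairs=hpairs)


def compute_feature_coefficients(
    pairs: ComparisonPairSet,
    mode: str = "pair_mean_over_variance",
    window: PixelWindow3x3 | None = None,
    fallback: float = 0.0,
) -> FeatureCoefficients:
    """Thresholds for the six pairs.

    Default mode: fcv_k = mean(x_k, y_k) / popvar(x_k, y_k), where the
    population variance of the two elements is ((x-y)/2)**2; *fallback*
    replaces an undefined ratio (equal elements).  ``global_sum`` sums the
    six per-pair terms into one shared value.  ``center_pixel`` copies the
    anchor intensities (requires *window*).
    """
    if mode not in COEFFICIENT_MODES:
        raise ConfigError(f"unknown coefficient_mode {mode!r}")
    ordered = pairs.ordered
    sigma2 = tuple(((x - y) / 2.0) ** 2 for x, y in ordered)
    if mode == "center_pixel":
        if window is None:
            raise ValueError("center_pixel mode needs the window")
        SL, SC, SR = window.SL, window.SC, window.SR
        fcv = (SC[0], SC[1], SC[2], SL[1], SC[1], SR[1])
        return FeatureCoefficients(fcv=fcv, sigma2=sigma2)
    terms = tuple(
        ((x + y) / 2.0) / s2 if s2 > 0 else fallback
        for (x, y), s2 in zip(ordered, sigma2)
    )
    if mode == "global_sum":
        total = sum(terms)
        terms = (total,) * 6
    return FeatureCoefficients(fcv=terms, sigma2=sigma2)


def binarize_pairs(pairs: ComparisonPairSet, coeffs: FeatureCoefficients) -> BinaryPairSet:
    """Threshold each pair element against its coefficient; ties give 1."""
    bits = tuple(
        (int(x - f >= 0), int(y - f >= 0))
        for (x, y), f in zip(pairs.ordered, coeffs.fcv)
    )
    return BinaryPairSet(vbp=bits[:3], hbp=bits[3:])


def symmetric_split(bpairs: BinaryPairSet) -> SplitMatrices:
    """Place the bit pairs into two 3x3 matrices and OR-merge them.

    Vertical pair i fills row i's left/right cells; horizontal pair j fills
    column j's top/bottom cells.  The centre cell of the merge is always 0.
    """
    vertical = np.zeros((3, 3), dtype=np.uint8)
    horizontal = np.zeros((3, 3), dtype=np.uint8)
    for i, (first, second) in enumerate(bpairs.vbp):
        vertical[i, 0] = first
        vertical[i, 2] = second
    for j, (first, second) in enumerate(bpairs.hbp):
        horizontal[0, j] = first
        horizontal[2, j] = second
    return SplitMatrices(vertical=vertical, horizontal=horizontal)


def flatten_clockwise(merged) -> tuple[int, ...]:
    """The 8 perimeter bits, clockwise from top-left; the centre is skipped."""
    m = np.asarray(merged)
    if m.shape != (3, 3):
        raise ValueError(f"expected a 3x3 grid, got {m.shape}")
    return tuple(int(m[r, c]) for r, c in CLOCKWISE_PERIMETER)


def weighted_pixel_value(bits: Sequence[int], bit_order: str = "lsb_at_top_left") -> int:
    """Decimal value of the 8-bit code; first bit is LSB by default."""
    if len(bits) != 8:
        raise ValueError("need exactly 8 bits")
    if bit_order not in BIT_ORDERS:
        raise ConfigError(f"unknown bit_order {bit_order!r}")
    if bit_order == "lsb_at_top_left":
        return sum(int(b) << i for i, b in enumerate(bits))
    return sum(int(b) << (7 - i) for i, b in enumerate(bits))


def sim_lbp_pixel(window: PixelWindow3x3, config: TransformConfig = TransformConfig()) -> int:
    """The full per-pixel pipeline: pairs -> coefficients -> bits -> split -> code."""
    pairs = compute_comparison_pairs(window, config.sign_convention)
    coeffs = compute_feature_coefficients(
        pairs, config.coefficient_mode, window, config.zero_variance_fallback
    )
    bpairs = binarize_pairs(pairs, coeffs)
    split = symmetric_split(bpairs)
    code = flatten_clockwise(split.merged)
    return weighted_pixel_value(code, config.bit_order)


# ---------------------------------------------------------------------------
# whole-image application
# ---------------------------------------------------------------------------

def _output_geometry(img: np.ndarray, padding: str) -> tuple[np.ndarray, int, int]:
    """Padded float array plus output height/width for a padding mode."""
    h, w = img.shape
    if padding == "crop":
        if h < 3 or w < 3:
            raise ValueError("crop padding needs an image of at least 3x3")
        return img.astype(float), h - 2, w - 2
    return np.pad(img.astype(float), 1, mode=_NP_PAD_MODE[padding]), h, w


def sim_lbp_transform(image, config: TransformConfig = TransformConfig()) -> np.ndarray:
    """Apply the SIM-LBP descriptor to every pixel of *image*.

    Returns a fresh uint8 image (the input is never modified, so every
    window reads original neighbours).  Output size equals input size except
    under ``crop`` padding, where the 1-pixel border is dropped.
    """
    img = as_gray_image(image)
    P, oh, ow = _output_geometry(img, config.padding)
    S = [[P[r : r + oh, c : c + ow] for c in range(3)] for r in range(3)]
    s = 1.0 if config.sign_convention == "neighbor_minus_center" else -1.0

    # six (x, y) pairs in canonical order V1,V2,V3,H1,H2,H3
    xs = [s * (S[i][0] - S[i][1]) for i in range(3)]
    ys = [s * (S[i][2] - S[i][1]) for i in range(3)]
    xs += [s * (S[0][j] - S[1][j]) for j in range(3)]
    ys += [s * (S[2][j] - S[1][j]) for j in range(3)]

    if config.coefficient_mode == "center_pixel":
        fcv = [S[0][1], S[1][1], S[2][1], S[1][0], S[1][1], S[1][2]]
    else:
        terms = []
        for x, y in zip(xs, ys):
            s2 = ((x - y) / 2.0) ** 2
            m = (x + y) / 2.0
            t = np.divide(m, s2, out=np.full_like(m, config.zero_variance_fallback),
                          where=s2 > 0)
            terms.append(t)
        if config.coefficient_mode == "global_sum":
            total = sum(terms)
            fcv = [total] * 6
        else:
            fcv = terms

    bx = [(x - f >= 0) for x, f in zip(xs, fcv)]
    by = [(y - f >= 0) for y, f in zip(ys, fcv)]

    # merged perimeter cells, clockwise TL,TC,TR,MR,BR,BC,BL,ML;
    # vertical split contributes (row i: x->left, y->right), horizontal
    # split (column j: x->top, y->bottom); centre cell never populated.
    bits = [
        bx[0] | bx[3],  # TL: V1 left  | H(L) top
        bx[4],          # TC: H(C) top
        by[0] | bx[5],  # TR: V1 right | H(R) top
        by[1],          # MR: V2 right
        by[2] | by[5],  # BR: V3 right | H(R) bottom
        by[4],          # BC: H(C) bottom
        bx[2] | by[3],  # BL: V3 left  | H(L) bottom
        bx[1],          # ML: V2 left
    ]
    if config.bit_order == "lsb_at_top_left":
        weights = [1 << i for i in range(8)]
    else:
        weights = [1 << (7 - i) for i in range(8)]
    out = np.zeros((oh, ow), dtype=np.int64)
    for b, wgt in zip(bits, weights):
        out += b.astype(np.int64) * wgt
    return out.astype(np.uint8)


def sim_lbp_transform_naive(image, config: TransformConfig = TransformConfig()) -> np.ndarray:
    """Literal per-pixel composition of the stage functions (reference oracle)."""
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
            window = extract_window(img, r, c, config.padding)
            out[oi, oj] = sim_lbp_pixel(window, config)
    return out
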