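"""Grid-cell histogram features and look-up windows.

A transformed (or raw) image is partitioned into a rectangular grid of
near-equal cells; each cell contributes a normalised intensity histogram.
Named look-up windows select sub-rectangles of cells (a facial-feature
region such as an eye or the mouth) and concatenate their histograms into
a feature vector.  A chi-square distance and a nearest-neighbour rule give
a minimal histogram-matching classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .transform import as_gray_image

__all__ = [
    "CellGridSpec",
    "CellHistogramGrid",
    "LookupWindow",
    "cell_histograms",
    "lookup_feature",
    "chi_square_distance",
    "nearest_neighbor_label",
    "default_lookup_windows",
    "load_lookup_windows",
    "save_lookup_windows",
]


@dataclass(frozen=True)
class CellGridSpec:
    """Grid geometry: rows x cols cells, histograms of *bins* bins.

    Bin b collects intensities v with floor(v * bins / 256) == b, so the
    default 256 bins is the identity binning on 8-bit codes.
    """

    grid_rows: int = 8
    grid_cols: int = 8
    bins: int = 256

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must have at least one cell")
        if not 2 <= self.bins <= 256:
            raise ValueError("bins must lie in [2, 256]")

    def cell_slices(self, height: int, width: int) -> list[list[tuple[slice, slice]]]:
        """Row-major (row_slice, col_slice) per cell; remainder pixels go to
        the last row/column of cells so the partition is exact."""
        if height < self.grid_rows or width < self.grid_cols:
            raise ValueError(
                f"image {height}x{width} smaller than grid "
                f"{self.grid_rows}x{self.grid_cols}"
            )
        rstep, cstep = height // self.grid_rows, width // self.grid_cols
        redges = [i * rstep for i in range(self.grid_rows)] + [height]
        cedges = [j * cstep for j in range(self.grid_cols)] + [width]
        return [
            [
                (slice(redges[i], redges[i + 1]), slice(cedges[j], cedges[j + 1]))
                for j in range(self.grid_cols)
            ]
            for i in range(self.grid_rows)
        ]


@dataclass(frozen=True)
class CellHistogramGrid:
    """Per-cell normalised histograms (rows x cols x bins) plus pixel counts."""

    spec: CellGridSpec
    histograms: np.ndarray
    counts: np.ndarray

    def flatten(self) -> np.ndarray:
        """All cells' histograms concatenated row-major."""
        return self.histograms.reshape(-1)


@dataclass(frozen=True)
class LookupWindow:
    """A named half-open rectangle of grid cells (a facial-feature region)."""

    name: str
    row_range: tuple[int, int]
    col_range: tuple[int, int]

    def __post_init__(self) -> None:
        for lo, hi in (self.row_range, self.col_range):
            if hi <= lo or lo < 0:
                raise ValueError(f"window {self.name!r}: empty or negative range")


def cell_histograms(image, spec: CellGridSpec = CellGridSpec()) -> CellHistogramGrid:
    """Partition *image* into the grid and histogram each cell.

    Every cell histogram sums to 1 (cells are never empty by construction);
    count-weighted cell histograms recombine exactly to the image's global
    histogram.
    """
    img = as_gray_image(image)
    h, w = img.shape
    binned = (img.astype(np.int64) * spec.bins) // 256
    hists = np.zeros((spec.grid_rows, spec.grid_cols, spec.bins), dtype=float)
    counts = np.zeros((spec.grid_rows, spec.grid_cols), dtype=np.int64)
    for i, row in enumerate(spec.cell_slices(h, w)):
        for j, (rs, cs) in enumerate(row):
            cell = binned[rs, cs].ravel()
            counts[i, j] = cell.size
            hists[i, j] = np.bincount(cell, minlength=spec.bins) / cell.size
    return CellHistogramGrid(spec=spec, histograms=hists, counts=counts)


def lookup_feature(gridfeat: CellHistogramGrid, window: LookupWindow) -> np.ndarray:
    """Concatenate the selected cells' histograms in row-major order."""
    spec = gridfeat.spec
    r0, r1 = window.row_range
    c0, c1 = window.col_range
    if r1 > spec.grid_rows or c1 > spec.grid_cols:
        raise IndexError(
            f"window {window.name!r} rows {window.row_range} cols {window.col_range} "
            f"outside a {spec.grid_rows}x{spec.grid_cols} grid"
        )
    return gridfeat.histograms[r0:r1, c0:c1].reshape(-1).copy()


def chi_square_distance(h1, h2) -> float:
    """sum_b (h1_b - h2_b)^2 / (h1_b + h2_b); zero-denominator terms skipped."""
    a = np.asarray(h1, dtype=float).ravel()
    b = np.asarray(h2, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    denom = a + b
    mask = denom != 0
    d = a[mask] - b[mask]
    return float(np.sum(d * d / denom[mask]))


def nearest_neighbor_label(query, references: Iterable[tuple[object, Sequence[float]]]):
    """Label of the reference minimising chi-square distance.

    Ties break toward the earliest reference in iteration order.
    """
    best_label, best_d = None, np.inf
    n = 0
    for label, vec in references:
        n += 1
        d = chi_square_distance(query, vec)
        if d < best_d:
            best_label, best_d = label, d
    if n == 0:
        raise ValueError("need at least one reference")
    return best_label


# ---------------------------------------------------------------------------
# look-up window templates
# ---------------------------------------------------------------------------

def default_lookup_windows() -> list[LookupWindow]:
    """Heuristic facial-feature template for a frontal face on an 8x8 grid
    (eyes/brows upper-middle, nose centre, mouth lower-middle).  Cell
    coordinates, not pixels, so it applies at any image resolution."""
    text = resources.files("simlbp.data").joinpath("lookup_windows_8x8.json").read_text()
    return _windows_from_json(json.loads(text))


def _windows_from_json(obj: dict) -> list[LookupWindow]:
    return [
        LookupWindow(name=name, row_range=tuple(spec["rows"]), col_range=tuple(spec["cols"]))
        for name, spec in obj.items()
    ]


def load_lookup_windows(path) -> list[LookupWindow]:
    with open(path) as fh:
        return _windows_from_json(json.load(fh))


def save_lookup_windows(windows: Iterable[LookupWindow], path) -> None:
    obj = {
        w.name: {"rows": list(w.row_range), "cols": list(w.col_range)} for w in windows
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")
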