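"""Image and config file I/O.

Reads PNG/PGM/JPEG; multi-channel inputs are reduced to luma with the
ITU-R 601 weights 0.299/0.587/0.114 (Pillow's "L" conversion).  Writes
PNG/PGM only — transformed images are codes, so lossy formats are refused.
TransformConfig round-trips through a flat TOML file.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

import numpy as np
from PIL import Image

from .baseline import LbpConfig
from .transform import TransformConfig, as_gray_image

__all__ = ["read_gray", "write_gray", "load_config", "save_config"]

_WRITABLE = {".png", ".pgm", ".ppm"}


def read_gray(path) -> np.ndarray:
    """Load an image as a 2-D uint8 array (luma conversion if needed)."""
    with Image.open(path) as im:
        if im.mode != "L":
            im = im.convert("L")  # ITU-R 601: 0.299 R + 0.587 G + 0.114 B
        return np.asarray(im, dtype=np.uint8)


def write_gray(path, image) -> None:
    """Write a grayscale image losslessly (PNG or PGM; JPEG refused)."""
    path = Path(path)
    if path.suffix.lower() not in _WRITABLE:
        raise ValueError(
            f"refusing lossy/unknown output format {path.suffix!r}; use .png or .pgm"
        )
    Image.fromarray(as_gray_image(image), mode="L").save(path)


def load_config(path) -> TransformConfig:
    """Read a TransformConfig from a flat TOML file; absent keys keep defaults."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(TransformConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return TransformConfig(**data)


def save_config(config: TransformConfig | LbpConfig, path) -> None:
    """Write a config as flat TOML key = value lines."""
    lines = []
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        lines.append(f'{f.name} = "{v}"' if isinstance(v, str) else f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")
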