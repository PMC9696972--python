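"""Synthetic grayscale face phantoms.

Procedurally drawn frontal-face images — a mid-gray oval face on a dark
background with elliptical eyes, angled brow strokes and a curved mouth —
followed by a linear illumination ramp, Gaussian blur and additive Gaussian
noise.  Every image is fully determined by its :class:`FacePhantomSpec`, so
descriptor claims (illumination robustness, blur/noise degradation) are
testable without any face-image dataset.

The phantoms emulate single-channel frontal expression photographs only in
the coarse layout of facial features; they have no skin texture, pose
variation or identity structure, so results on them speak to the descriptor
arithmetic, not to real-face performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .transform import as_gray_image

__all__ = [
    "FacePhantomSpec",
    "LabeledImageSet",
    "SpecError",
    "generate_face_phantom",
    "generate_dataset",
    "apply_illumination",
    "DEFAULT_CLASS_SPECS",
    "DEFAULT_JITTER",
]

# drawing intensities (8-bit): background, face oval, feature "ink"
_BACKGROUND = 30.0
_FACE = 150.0
_INK = 60.0


class SpecError(ValueError):
    """Phantom geometry places a feature outside the frame."""


@dataclass(frozen=True)
class FacePhantomSpec:
    """Everything that determines one phantom image.

    Geometry fields are fractions of the image size; ``illumination_offset``
    is added uniformly, ``illumination_gradient`` ramps linearly left to
    right across the full width (both in intensity units).  ``seed`` drives
    the noise generator only.
    """

    height: int = 128
    width: int = 128
    eye_sep: float = 0.30          # fraction of width between eye centres
    brow_angle: float = 0.0        # degrees; positive raises the outer ends
    mouth_curvature: float = 0.0   # positive = smile-like arc, negative = frown
    illumination_offset: float = 0.0
    illumination_gradient: float = 0.0
    blur_sigma: float = 1.0        # pixels
    noise_sd: float = 2.0          # intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise SpecError("phantom must be at least 32x32")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise SpecError("blur_sigma and noise_sd must be >= 0")


@dataclass(frozen=True)
class LabeledImageSet:
    """Parallel images / labels / specs; regenerable bit-identically from specs."""

    images: tuple[np.ndarray, ...]
    labels: tuple[object, ...]
    specs: tuple[FacePhantomSpec, ...]

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.labels) == len(self.specs)):
            raise ValueError("images, labels and specs must be parallel")

    def __len__(self) -> int:
        return len(self.images)


def _disk_ellipse(rows, cols, cy, cx, ry, rx) -> np.ndarray:
    return ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0


def _stroke(canvas: np.ndarray, r0, c0, r1, c1, thickness: float, value: float) -> None:
    """Draw a straight stroke by dense sampling (no antialiasing needed)."""
    n = int(4 * max(abs(r1 - r0), abs(c1 - c0), 1))
    t = np.linspace(0.0, 1.0, n)
    rr = r0 + (r1 - r0) * t
    cc = c0 + (c1 - c0) * t
    rad = max(int(round(thickness / 2)), 1)
    h, w = canvas.shape
    for r, c in zip(rr, cc):
        ir, ic = int(round(r)), int(round(c))
        canvas[max(ir - rad, 0) : min(ir + rad + 1, h),
               max(ic - rad, 0) : min(ic + rad + 1, w)] = value


def mouth_region(spec: FacePhantomSpec) -> tuple[slice, slice]:
    """Bounding rows/cols of the mouth arc (for region-difference checks)."""
    h, w = spec.height, spec.width
    half = 0.14 * w
    bend = abs(spec.mouth_curvature) * 0.08 * h
    r0 = int(0.72 * h - bend - 0.04 * h) - 1
    r1 = int(0.72 * h + bend + 0.04 * h) + 2
    c0 = int(0.5 * w - half) - 2
    c1 = int(0.5 * w + half) + 3
    return slice(max(r0, 0), min(r1, h)), slice(max(c0, 0), min(c1, w))


def _draw_base(spec: FacePhantomSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((h, w), _BACKGROUND)

    # face oval
    img[_disk_ellipse(rows, cols, 0.50 * h, 0.50 * w, 0.44 * h, 0.38 * w)] = _FACE

    # eyes
    eye_r = 0.40 * h
    eye_dx = spec.eye_sep / 2.0 * w
    eye_cols = (0.5 * w - eye_dx, 0.5 * w + eye_dx)
    for ec in eye_cols:
        if not (0.15 * w < ec < 0.85 * w):
            raise SpecError(f"eye centre column {ec:.1f} out of frame")
        img[_disk_ellipse(rows, cols, eye_r, ec, 0.045 * h, 0.065 * w)] = _INK

    # brows: strokes above the eyes, outer end raised by +brow_angle
    brow_r = 0.31 * h
    half = 0.085 * w
    thick = max(h / 64.0, 1.0)
    dr = np.tan(np.deg2rad(spec.brow_angle)) * half
    for side, ec in zip((-1, +1), eye_cols):
        # inner end sits at brow_r + dr/2, outer (toward the image edge) at
        # brow_r - dr/2, so positive brow_angle raises both outer ends
        inner_c, outer_c = ec - side * half, ec + side * half
        _stroke(img, brow_r + dr / 2, inner_c, brow_r - dr / 2, outer_c, thick, _INK)

    # mouth: parabolic arc, positive curvature bends the ends upward (smile)
    mr, mc, mhalf = 0.72 * h, 0.50 * w, 0.14 * w
    bend = spec.mouth_curvature * 0.08 * h
    if not (0.55 * h < mr + abs(bend) < 0.95 * h):
        raise SpecError("mouth out of frame")
    xs = np.linspace(-1.0, 1.0, int(8 * mhalf))
    rad = max(int(round(thick / 2)), 1)
    for x in xs:
        r = int(round(mr + bend * (1.0 - x * x)))
        c = int(round(mc + x * mhalf))
        img[max(r - rad, 0) : r + rad + 1, max(c - rad, 0) : c + rad + 1] = _INK
    return img


def generate_face_phantom(spec: FacePhantomSpec) -> np.ndarray:
    """Render the phantom: geometry, illumination, blur, noise, clip, uint8."""
    img = _draw_base(spec)
    h, w = img.shape
    ramp = spec.illumination_offset + spec.illumination_gradient * (
        np.arange(w, dtype=float) / w
    )
    img = img + ramp[None, :]
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma, mode="nearest")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# demo study conditions: two expression classes separated by mouth curvature
DEFAULT_CLASS_SPECS: Mapping[str, FacePhantomSpec] = {
    "smile": FacePhantomSpec(mouth_curvature=+0.5),
    "frown": FacePhantomSpec(mouth_curvature=-0.5),
}

# geometry-only jitter: illumination/blur/noise stay at the template values
# so perturbation experiments control those factors explicitly
DEFAULT_JITTER: Mapping[str, float] = {
    "eye_sep": 0.01,
    "brow_angle": 3.0,
    "mouth_curvature": 0.08,
}

_JITTERABLE = (
    "eye_sep", "brow_angle", "mouth_curvature",
    "illumination_offset", "illumination_gradient", "blur_sigma", "noise_sd",
)


def generate_dataset(
    n_per_class: int,
    class_specs: Mapping[object, FacePhantomSpec] = DEFAULT_CLASS_SPECS,
    jitter: Mapping[str, float] = DEFAULT_JITTER,
    seed: int = 0,
) -> LabeledImageSet:
    """n_per_class phantoms per class, geometry jittered around each template.

    One seeded generator drives all jitter and per-image noise seeds, so the
    whole set regenerates bit-identically from (arguments, seed).  Classes
    are processed in iteration order of *class_specs*.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    bad = set(jitter) - set(_JITTERABLE)
    if bad:
        raise ValueError(f"cannot jitter fields: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    images, labels, specs = [], [], []
    for label, template in class_specs.items():
        for _ in range(n_per_class):
            changes = {
                name: getattr(template, name) + rng.normal(0.0, sd)
                for name, sd in jitter.items()
                if sd > 0
            }
            for name in ("blur_sigma", "noise_sd"):
                if name in changes:
                    changes[name] = max(changes[name], 0.0)
            spec = replace(template, seed=int(rng.integers(0, 2**31)), **changes)
            images.append(generate_face_phantom(spec))
            labels.append(label)
            specs.append(spec)
    return LabeledImageSet(images=tuple(images), labels=tuple(labels), specs=tuple(specs))


def apply_illumination(image, offset: float, gradient: float = 0.0) -> np.ndarray:
    """out(r, c) = clip(in(r, c) + offset + gradient * c / width); pure."""
    img = as_gray_image(image)
    w = img.shape[1]
    ramp = offset + gradient * (np.arange(w, dtype=float) / w)
    return np.clip(np.rint(img.astype(float) + ramp[None, :]), 0, 255).astype(np.uint8)
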