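"""Crop, upscale and coordinate transforms into the large mining frame.

All patch mining happens on "large" images: the raw unfolded-rib image is
cropped to a fixed window (default 500 rows x 1000 columns, removing the
black background around the rib fan) and then enlarged to 300% with
pixel-area-relation resampling, yielding the default 1500 x 3000 frame. For
an integer enlargement factor, area-relation resampling is exact block
replication — every output pixel's footprint lies inside exactly one source
pixel — so constant regions and mean intensities are preserved exactly.

Coordinate convention, fixed for the whole package: 0-based, ``x`` = column
(left to right), ``y`` = row (top to bottom). An annotation made in the
cropped frame maps to the center of its ``factor x factor`` block in the
large frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import BoundsError, ConfigError

STAGES = ("raw", "cropped", "large")


@dataclass(frozen=True)
class UnfoldedImage:
    """One unfolded rib cage: a 2-D grayscale grid plus provenance.

    ``stage`` tracks where the image sits in the preprocessing chain:
    ``raw`` (as generated/exported), ``cropped`` (background removed) or
    ``large`` (upscaled mining frame).
    """

    image_id: str
    pixels: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ConfigError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if np.ndim(self.pixels) != 2:
            raise ConfigError("pixels must be a 2-D grayscale grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CropSpec:
    """Axis-aligned crop window: top-left corner plus height/width."""

    top: int = 0
    left: int = 0
    height: int = 500
    width: int = 1000

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ConfigError("crop height and width must be positive")
        if self.top < 0 or self.left < 0:
            raise ConfigError("crop origin must be non-negative")


def crop_image(img: UnfoldedImage, spec: CropSpec) -> UnfoldedImage:
    """Cut the crop window out of a raw image.

    Output pixel ``(r, c)`` equals input pixel ``(r + top, c + left)``.
    """
    h, w = img.shape
    if spec.top + spec.height > h or spec.left + spec.width > w:
        raise BoundsError(
            f"crop window {spec} exceeds raw image bounds {h}x{w} for {img.image_id!r}"
        )
    window = img.pixels[spec.top : spec.top + spec.height, spec.left : spec.left + spec.width]
    return replace(img, pixels=window.copy(), stage="cropped")


def upscale_image(img: UnfoldedImage, factor: int = 3) -> UnfoldedImage:
    """Enlarge a cropped image by an integer factor (area-relation resampling).

    ``factor=1`` is the identity. Each source pixel becomes a
    ``factor x factor`` constant block.
    """
    if factor < 1:
        raise ConfigError(f"upscale factor must be >= 1, got {factor}")
    if factor == 1:
        return replace(img, stage="large")
    big = np.repeat(np.repeat(img.pixels, factor, axis=0), factor, axis=1)
    return replace(img, pixels=big, stage="large")


def to_large_coords(
    x: int, y: int, spec: CropSpec, factor: int = 3
) -> tuple[int, int]:
    """Map a cropped-frame annotation to the large frame.

    The point lands on the center of its block:
    ``X = (x - left) * factor + (factor - 1) // 2`` (and analogously for Y).
    """
    if not (spec.left <= x < spec.left + spec.width and spec.top <= y < spec.top + spec.height):
        raise BoundsError(f"point ({x}, {y}) lies outside the crop window {spec}")
    off = (factor - 1) // 2
    return (x - spec.left) * factor + off, (y - spec.top) * factor + off


def from_large_coords(
    X: int, Y: int, spec: CropSpec, factor: int = 3
) -> tuple[int, int]:
    """Inverse of :func:`to_large_coords` (recovers the cropped-frame point)."""
    off = (factor - 1) // 2
    return (X - off) // factor + spec.left, (Y - off) // factor + spec.top


def load_image(path: str | Path, image_id: str | None = None, stage: str = "raw") -> UnfoldedImage:
    """Read a grayscale PNG/TIFF into an :class:`UnfoldedImage`."""
    p = Path(path)
    pixels = np.asarray(Image.open(p).convert("L"))
    return UnfoldedImage(image_id=image_id or p.stem, pixels=pixels, stage=stage)


def save_image(img: UnfoldedImage, path: str | Path) -> None:
    Image.fromarray(np.asarray(img.pixels, dtype=np.uint8), mode="L").save(Path(path))
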