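"""Mining of labeled 99x99 patches from large unfolded-rib images.

Positives are centered on annotated fractures and augmented by sliding the
window from the center in the four cardinal directions in 10-pixel steps
(default four steps per direction, i.e. 16 additional samples per fracture).
Shifted samples in which the motif is mostly lost are discarded by a
curation predicate; the default predicate keeps a sample iff the fracture's
extent box overlaps the patch window by at least a configurable fraction.

Negatives come from fracture-free images via a sliding window with 25-pixel
stride along both axes; each negative is its own aggregation group, while
all representations of one fracture share a single group id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import BoundsError, ConfigError, DataError
from .preprocessing import UnfoldedImage
from .synthetic import FractureAnnotation

logger = logging.getLogger(__name__)

PATCH_SIZE = 99
NEGATIVE_STRIDE = 25


@dataclass
class PatchSample:
    """One 99x99 training sample with its provenance and aggregation group."""

    patch: np.ndarray
    label: str
    image_id: str
    group_id: str
    center: tuple[int, int]  # (X, Y) in large-image coordinates
    shift: tuple[int, int] = (0, 0)  # (dx, dy) relative to the annotated center


@dataclass(frozen=True)
class ShiftScheme:
    """Cardinal-direction shift augmentation: ``steps_per_direction`` steps of
    ``step`` pixels along each of up/down/left/right."""

    step: int = 10
    steps_per_direction: int = 4

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ConfigError("shift step must be positive")
        if self.steps_per_direction < 0:
            raise ConfigError("steps_per_direction must be >= 0")

    @property
    def n_shifts(self) -> int:
        return 4 * self.steps_per_direction


def extract_patch(
    img: UnfoldedImage | np.ndarray, center: tuple[int, int], size: int = PATCH_SIZE
) -> np.ndarray:
    """Pixel-exact copy of the ``size x size`` window centered on ``(X, Y)``.

    Raises :class:`BoundsError` when the window crosses the image border;
    the caller decides whether to skip the sample.
    """
    if size % 2 != 1:
        raise ConfigError(f"patch size must be odd, got {size}")
    pixels = img.pixels if isinstance(img, UnfoldedImage) else np.asarray(img)
    X, Y = center
    half = size // 2
    h, w = pixels.shape
    if X - half < 0 or Y - half < 0 or X + half >= w or Y + half >= h:
        raise BoundsError(f"patch window at ({X}, {Y}) crosses the {h}x{w} image border")
    return pixels[Y - half : Y + half + 1, X - half : X + half + 1].copy()


def augment_centers(
    center: tuple[int, int], scheme: ShiftScheme = ShiftScheme()
) -> list[tuple[int, int, tuple[int, int]]]:
    """Additional window centers for one fracture: ``(X, Y, (dx, dy))``.

    Returns exactly ``4 * steps_per_direction`` distinct nonzero shifts; the
    original (unshifted) center is not included.
    """
    X, Y = center
    out = []
    for k in range(1, scheme.steps_per_direction + 1):
        d = k * scheme.step
        for dx, dy in ((d, 0), (-d, 0), (0, d), (0, -d)):
            out.append((X + dx, Y + dy, (dx, dy)))
    return out


CurationPredicate = Callable[[FractureAnnotation, tuple[int, int, int, int]], bool]


def box_overlap_curation(min_fraction: float = 0.5) -> CurationPredicate:
    """Curation rule: keep a shifted sample iff the fracture's extent box
    overlaps the patch window by at least ``min_fraction`` of the box area.

    Stands in for the manual removal of augmented samples that lost the
    fracture; ground-truth box overlap is the automatable proxy.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ConfigError("min_fraction must lie in [0, 1]")

    def predicate(ann: FractureAnnotation, window: tuple[int, int, int, int]) -> bool:
        bx0, by0, bx1, by1 = ann.extent_box
        wx0, wy0, wx1, wy1 = window
        ix = max(0, min(bx1, wx1) - max(bx0, wx0) + 1)
        iy = max(0, min(by1, wy1) - max(by0, wy0) + 1)
        box_area = (bx1 - bx0 + 1) * (by1 - by0 + 1)
        return ix * iy >= min_fraction * box_area

    return predicate


def accept_all(ann: FractureAnnotation, window: tuple[int, int, int, int]) -> bool:
    return True


def mine_fracture_samples(
    img: UnfoldedImage,
    annotations: Sequence[FractureAnnotation],
    scheme: ShiftScheme = ShiftScheme(),
    curation: CurationPredicate = accept_all,
    size: int = PATCH_SIZE,
) -> list[PatchSample]:
    """All retained patch samples for the fractures on one large image.

    Per fracture: the original centered sample plus up to
    ``scheme.n_shifts`` shifted ones, all sharing one group id. Shifted
    samples whose window leaves the image, or which fail the curation
    predicate, are dropped. A fracture whose *original* window is out of
    bounds is skipped entirely (with a warning) — there is nothing to learn
    from it.

    Annotation coordinates and extent boxes must already be in large-image
    coordinates.
    """
    half = size // 2
    samples: list[PatchSample] = []
    for j, ann in enumerate(annotations):
        group_id = f"{ann.image_id}_f{j:03d}"
        try:
            original = extract_patch(img, (ann.x, ann.y), size)
        except BoundsError:
            logger.warning(
                "fracture %s at (%d, %d) too close to the border; skipped",
                group_id,
                ann.x,
                ann.y,
            )
            continue
        samples.append(
            PatchSample(
                patch=original,
                label=ann.label,
                image_id=img.image_id,
                group_id=group_id,
                center=(ann.x, ann.y),
                shift=(0, 0),
            )
        )
        for X, Y, shift in augment_centers((ann.x, ann.y), scheme):
            try:
                patch = extract_patch(img, (X, Y), size)
            except BoundsError:
                continue
            window = (X - half, Y - half, X + half, Y + half)
            if not curation(ann, window):
                continue
            samples.append(
                PatchSample(
                    patch=patch,
                    label=ann.label,
                    image_id=img.image_id,
                    group_id=group_id,
                    center=(X, Y),
                    shift=shift,
                )
            )
    return samples


def negative_window_corners(
    shape: tuple[int, int], size: int = PATCH_SIZE, stride: int = NEGATIVE_STRIDE
) -> list[tuple[int, int]]:
    """Top-left corners ``(row, col)`` of the sliding-window grid: multiples
    of ``stride`` starting at (0, 0), fully-inside windows only."""
    h, w = shape
    if h < size or w < size:
        return []
    rows = range(0, h - size + 1, stride)
    cols = range(0, w - size + 1, stride)
    return [(r, c) for r in rows for c in cols]


def mine_negative_samples(
    img: UnfoldedImage,
    size: int = PATCH_SIZE,
    stride: int = NEGATIVE_STRIDE,
    annotations: Sequence[FractureAnnotation] = (),
) -> list[PatchSample]:
    """Sliding-window no-fracture samples from a fracture-free image.

    Each sample gets a unique group id (a negative is its own aggregation
    unit). Calling this on an annotated image is a contract violation.
    """
    if len(annotations) > 0:
        raise DataError(
            f"mine_negative_samples called on annotated image {img.image_id!r}"
        )
    half = size // 2
    samples = []
    for r, c in negative_window_corners(img.shape, size, stride):
        center = (c + half, r + half)
        samples.append(
            PatchSample(
                patch=img.pixels[r : r + size, c : c + size].copy(),
                label="no_fracture",
                image_id=img.image_id,
                group_id=f"{img.image_id}_neg_r{r}_c{c}",
                center=center,
            )
        )
    return samples


def balance_negatives(
    negatives: Sequence[PatchSample], n_target: int, seed: int
) -> list[PatchSample]:
    """Uniform random subset of negatives, without replacement, seeded."""
    if n_target > len(negatives):
        raise DataError(
            f"requested {n_target} negatives but only {len(negatives)} available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negatives), size=n_target, replace=False)
    return [negatives[i] for i in np.sort(idx)]
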