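"""Seeded generator of annotated unfolded-rib-cage images.

Real unfolded rib cages are 2-D curved-planar reformations of volumetric CT:
all ribs appear as bright, roughly horizontal bands on a dark background.
This module emulates that representation well enough to exercise every
downstream stage — patch mining, grouped splitting, training, aggregation and
hierarchical scoring — with exact ground truth and full seeded determinism.

Four fracture motifs are rendered, one per renderable fracture type:

* ``nondisplaced``      — a thin dark transverse line through the band,
  fragments not displaced;
* ``ad_latus``          — the distal band half offset sideways (vertically in
  the unfolded frame) by the motif magnitude;
* ``cum_contractione``  — longitudinal compression: the distal half slides
  over the proximal one, producing a brighter overlap zone;
* ``cum_distractione``  — longitudinal distraction: a dark gap of the motif
  magnitude between the fragments.

Everything is derived from ``(params.seed, image_id)``; the rib-band layout
and the pixel noise come from independent substreams, so the fracture-free
rendering of an image is pixel-identical outside the motif boxes.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigError, PlacementError
from .labels import FRACTURE_CLASSES
from .preprocessing import UnfoldedImage

ANNOTATION_COLUMNS = ["image_id", "x", "y", "label", "box_x0", "box_y0", "box_x1", "box_y1"]


def _default_class_mix() -> dict[str, float]:
    return {name: 0.25 for name in FRACTURE_CLASSES}


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic unfolded-rib generator.

    Defaults produce images at the post-crop geometry (500 rows x 1000
    columns) so the preprocessing crop is an identity unless padding is
    requested. Intensities are 8-bit grayscale; ``motif_magnitude`` is the
    offset/gap/overlap size in (pre-upscale) pixels.
    """

    image_height: int = 500
    image_width: int = 1000
    n_rib_bands: int = 8
    band_thickness: int = 9
    band_intensity: float = 180.0
    background_intensity: float = 20.0
    noise_sigma: float = 4.0
    motif_magnitude: int = 8
    fractures_per_image: int = 4
    class_mix: dict[str, float] = field(default_factory=_default_class_mix)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("class_mix probabilities must sum to 1 within 1e-9")
        unknown = set(self.class_mix) - set(FRACTURE_CLASSES)
        if unknown:
            raise ConfigError(f"class_mix contains non-fracture labels: {sorted(unknown)}")
        if self.motif_magnitude < 0:
            raise ConfigError("motif_magnitude must be >= 0")
        if self.band_thickness < 3:
            raise ConfigError("band_thickness must be >= 3")
        for name in ("band_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ConfigError(f"{name} must lie in [0, 255], got {v}")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.fractures_per_image < 0:
            raise ConfigError("fractures_per_image must be >= 0")


@dataclass(frozen=True)
class FractureAnnotation:
    """One fracture: its center pixel, terminal label and motif extent box.

    Coordinates are 0-based with ``x`` the column (from left) and ``y`` the
    row (from top). ``extent_box`` is the inclusive axis-aligned pixel box
    ``(x0, y0, x1, y1)`` covering the rendered motif; the center always lies
    inside it. Annotations mark fractures only, so the label is never
    ``no_fracture``.
    """

    image_id: str
    x: int
    y: int
    label: str
    extent_box: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.label not in FRACTURE_CLASSES:
            raise ConfigError(f"annotation label must be a fracture class, got {self.label!r}")
        x0, y0, x1, y1 = self.extent_box
        if not (x0 <= self.x <= x1 and y0 <= self.y <= y1):
            raise ConfigError("annotation center must lie inside its extent_box")


def _image_rngs(params: SimulationParams, image_id: str) -> tuple[np.random.Generator, ...]:
    # Independent substreams: band layout, noise, fracture placement. The
    # placement stream is consumed last so a fracture-free rerun reproduces
    # the identical base image.
    entropy = [params.seed & 0x7FFFFFFF, zlib.crc32(image_id.encode("utf-8"))]
    children = np.random.SeedSequence(entropy).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _band_centerlines(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Per-band center row as a function of column, shape (n_bands, width)."""
    h, w, n = params.image_height, params.image_width, params.n_rib_bands
    margin = params.band_thickness + params.motif_magnitude + 4
    base = np.linspace(margin, h - 1 - margin, n)
    x = np.arange(w)
    amp = rng.uniform(0.0, 2.5, size=n)
    phase = rng.uniform(0.0, 2 * np.pi, size=n)
    return base[:, None] + amp[:, None] * np.sin(2 * np.pi * x[None, :] / w + phase[:, None])


def _paint_bands(params: SimulationParams, centers: np.ndarray) -> np.ndarray:
    h, w = params.image_height, params.image_width
    canvas = np.full((h, w), params.background_intensity, dtype=np.float64)
    rows = np.arange(h)[:, None]
    half = params.band_thickness / 2.0
    for c in centers:
        mask = np.abs(rows - c[None, :]) <= half
        canvas[mask] = params.band_intensity
    return canvas


def render_motif(
    band_segment: np.ndarray,
    label: str,
    magnitude: int,
    background: float | None = None,
) -> np.ndarray:
    """Render one fracture motif into a band segment.

    ``band_segment`` is a 2-D intensity grid containing a roughly horizontal
    bright band; the fracture plane is the segment's center column. Returns a
    new float array; the input is not modified.
    """
    if label not in FRACTURE_CLASSES:
        raise ConfigError(f"unknown fracture label {label!r}")
    seg = np.asarray(band_segment, dtype=np.float64).copy()
    h, w = seg.shape
    cx = w // 2
    bg = float(np.min(seg)) if background is None else float(background)
    band = seg > (seg.max() + bg) / 2.0  # bright-band mask

    if label == "nondisplaced":
        # Thin dark transverse line; band geometry untouched on either side.
        cols = slice(max(cx - 1, 0), min(cx + 1, w))
        line = seg[:, cols]
        line[band[:, cols]] = bg
    elif label == "ad_latus":
        # Distal half offset vertically by `magnitude`.
        if magnitude >= h:
            raise PlacementError("ad_latus magnitude exceeds segment height")
        right = seg[:, cx:].copy()
        shifted = np.full_like(right, bg)
        if magnitude < h:
            shifted[magnitude:, :] = right[: h - magnitude, :]
        seg[:, cx:] = shifted
    elif label == "cum_contractione":
        # Overlapping fragments: a brighter zone of `magnitude` columns where
        # the two band halves stack (intensities add above background).
        z0 = max(cx - magnitude // 2, 0)
        z1 = min(z0 + magnitude, w)
        zone = seg[:, z0:z1]
        m = band[:, z0:z1]
        zone[m] = np.clip(2.0 * zone[m] - bg, 0.0, 255.0)
    elif label == "cum_distractione":
        # Dark gap of exactly `magnitude` columns through the band.
        g0 = max(cx - magnitude // 2, 0)
        g1 = min(g0 + magnitude, w)
        gap = seg[:, g0:g1]
        gap[band[:, g0:g1]] = bg
    return seg


def generate_image(
    params: SimulationParams, image_id: str
) -> tuple[UnfoldedImage, list[FractureAnnotation]]:
    """Generate one unfolded-rib image with exactly ``fractures_per_image``
    annotated fractures (at most one per band, bands chosen at random).

    Output is bit-identical for identical ``(params, image_id)``.
    """
    rng_bands, rng_noise, rng_place = _image_rngs(params, image_id)
    centers = _band_centerlines(params, rng_bands)
    canvas = _paint_bands(params, centers)
    noise = (
        rng_noise.normal(0.0, params.noise_sigma, size=canvas.shape)
        if params.noise_sigma > 0
        else 0.0
    )

    n_frac = params.fractures_per_image
    if n_frac > params.n_rib_bands:
        raise PlacementError(
            f"cannot place {n_frac} fractures on {params.n_rib_bands} bands "
            "(one fracture per band maximum)"
        )

    annotations: list[FractureAnnotation] = []
    if n_frac > 0:
        mag = params.motif_magnitude
        half_seg = max(34, 2 * mag + 10)
        x_margin = half_seg + 2
        if params.image_width <= 2 * x_margin:
            raise PlacementError("image too narrow to place fracture motifs")
        bands = sorted(rng_place.choice(params.n_rib_bands, size=n_frac, replace=False))
        labels = list(params.class_mix)
        probs = np.array([params.class_mix[k] for k in labels])
        for b in bands:
            x = int(rng_place.integers(x_margin, params.image_width - x_margin))
            label = labels[int(rng_place.choice(len(labels), p=probs))]
            y = int(round(centers[b, x]))
            th = params.band_thickness
            y_half = th // 2 + mag + 3
            r0, r1 = max(y - y_half, 0), min(y + y_half + 1, params.image_height)
            c0, c1 = x - half_seg, x + half_seg + 1
            segment = canvas[r0:r1, c0:c1]
            canvas[r0:r1, c0:c1] = render_motif(
                segment, label, mag, background=params.background_intensity
            )
            bx = max(mag, 2) + 3
            box = (
                max(x - bx, 0),
                max(y - y_half, 0),
                min(x + bx, params.image_width - 1),
                min(y + y_half, params.image_height - 1),
            )
            annotations.append(
                FractureAnnotation(image_id=image_id, x=x, y=y, label=label, extent_box=box)
            )

    pixels = np.clip(canvas + noise, 0.0, 255.0).astype(np.uint8)
    return UnfoldedImage(image_id=image_id, pixels=pixels, stage="raw"), annotations


def annotations_to_frame(annotations: list[FractureAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "image_id": a.image_id,
            "x": a.x,
            "y": a.y,
            "label": a.label,
            "box_x0": a.extent_box[0],
            "box_y0": a.extent_box[1],
            "box_x1": a.extent_box[2],
            "box_y1": a.extent_box[3],
        }
        for a in annotations
    ]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def annotations_from_frame(df: pd.DataFrame) -> list[FractureAnnotation]:
    return [
        FractureAnnotation(
            image_id=str(r.image_id),
            x=int(r.x),
            y=int(r.y),
            label=str(r.label),
            extent_box=(int(r.box_x0), int(r.box_y0), int(r.box_x1), int(r.box_y1)),
        )
        for r in df.itertuples(index=False)
    ]


def generate_dataset(
    params: SimulationParams,
    n_positive_images: int,
    n_negative_images: int,
    out_dir: str | Path,
) -> dict:
    """Write a seeded corpus of positive and negative images to ``out_dir``.

    Produces one PNG per image, a single ``annotations.csv`` covering the
    positives, and a JSON manifest listing every file with its role. Reruns
    with identical arguments are byte-identical.
    """
    if n_positive_images < 0 or n_negative_images < 0:
        raise ConfigError("image counts must be >= 0")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    neg_params = SimulationParams(**{**asdict(params), "fractures_per_image": 0})

    entries = []
    all_annotations: list[FractureAnnotation] = []
    for role, count, p in (
        ("positive", n_positive_images, params),
        ("negative", n_negative_images, neg_params),
    ):
        for i in range(count):
            image_id = f"{role[:3]}_{i:04d}"
            img, anns = generate_image(p, image_id)
            path = out / f"{image_id}.png"
            Image.fromarray(img.pixels, mode="L").save(path)
            entries.append({"image_id": image_id, "path": path.name, "role": role})
            all_annotations.extend(anns)

    ann_path = out / "annotations.csv"
    annotations_to_frame(all_annotations).to_csv(ann_path, index=False)

    manifest = {
        "params": {**asdict(params), "class_mix": dict(params.class_mix)},
        "n_positive_images": n_positive_images,
        "n_negative_images": n_negative_images,
        "images": entries,
        "annotations_csv": ann_path.name,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
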