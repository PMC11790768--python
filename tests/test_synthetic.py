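"""The synthetic unfolded-rib generator: determinism, annotation contracts,
and the geometric signatures of the four fracture motifs."""

import dataclasses

import numpy as np
import pytest

from ribfrac.errors import ConfigError, PlacementError
from ribfrac.synthetic import (
    FractureAnnotation,
    SimulationParams,
    generate_dataset,
    generate_image,
    render_motif,
)


def _clean_band(height=40, width=80, top=17, bottom=26, band=180.0, bg=20.0):
    seg = np.full((height, width), bg)
    seg[top:bottom, :] = band
    return seg


def _band_centroid(seg, col, thresh=100.0):
    rows = np.nonzero(seg[:, col] > thresh)[0]
    assert rows.size > 0, f"no band pixels in column {col}"
    return rows.mean()


class TestSimulationParams:
    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimulationParams(class_mix={"nondisplaced": 0.5, "ad_latus": 0.2})

    def test_intensities_and_thickness_validated(self):
        with pytest.raises(ConfigError):
            SimulationParams(band_intensity=300.0)
        with pytest.raises(ConfigError):
            SimulationParams(band_thickness=2)
        with pytest.raises(ConfigError):
            SimulationParams(motif_magnitude=-1)


class TestGenerateImage:
    def test_no_fractures_requested_gives_empty_annotations(self):
        p = SimulationParams(fractures_per_image=0)
        _, anns = generate_image(p, "img")
        assert anns == []

    def test_seeded_determinism(self):
        p = SimulationParams(seed=11)
        a, _ = generate_image(p, "img")
        b, _ = generate_image(p, "img")
        assert np.array_equal(a.pixels, b.pixels)

    def test_degenerate_class_mix(self):
        p = SimulationParams(
            class_mix={"cum_distractione": 1.0}, fractures_per_image=3
        )
        _, anns = generate_image(p, "img")
        assert [a.label for a in anns] == ["cum_distractione"] * 3

    def test_requested_count_and_annotation_contracts(self):
        p = SimulationParams(seed=5, fractures_per_image=4)
        img, anns = generate_image(p, "img")
        # fracture-free rendering of the same image: centers must be on bands
        base, _ = generate_image(dataclasses.replace(p, fractures_per_image=0), "img")
        assert len(anns) == 4
        h, w = img.shape
        for a in anns:
            x0, y0, x1, y1 = a.extent_box
            assert 0 <= x0 <= a.x <= x1 < w
            assert 0 <= y0 <= a.y <= y1 < h
            # the annotated center lies on a rib band (bright before the
            # motif is cut in; a gap motif may darken the center itself)
            assert base.pixels[a.y - 1 : a.y + 2, a.x - 1 : a.x + 2].max() > 100

    def test_too_many_fractures_raises_placement_error(self):
        p = SimulationParams(n_rib_bands=3, fractures_per_image=4)
        with pytest.raises(PlacementError):
            generate_image(p, "img")

    def test_motif_changes_pixels_inside_every_extent_box(self):
        p = SimulationParams(seed=9, fractures_per_image=4)
        img, anns = generate_image(p, "img")
        p0 = dataclasses.replace(p, fractures_per_image=0)
        base, _ = generate_image(p0, "img")
        diff = img.pixels.astype(int) - base.pixels.astype(int)
        for a in anns:
            x0, y0, x1, y1 = a.extent_box
            assert np.abs(diff[y0 : y1 + 1, x0 : x1 + 1]).sum() > 0


class TestRenderMotif:
    def test_nondisplaced_keeps_band_centers(self):
        seg = _clean_band()
        out = render_motif(seg, "nondisplaced", 5)
        # dark transverse line at the fracture plane
        assert (out[17:26, 39:41] <= 20.0).all()
        # vertical band centers unchanged on both sides of the line
        assert _band_centroid(out, 5) == _band_centroid(seg, 5)
        assert _band_centroid(out, 75) == _band_centroid(seg, 75)

    @pytest.mark.parametrize("magnitude", [4, 6, 10])
    def test_ad_latus_offsets_band_center_by_magnitude(self, magnitude):
        out = render_motif(_clean_band(), "ad_latus", magnitude)
        delta = _band_centroid(out, 70) - _band_centroid(out, 10)
        assert delta == pytest.approx(magnitude)

    @pytest.mark.parametrize("magnitude", [6, 8])
    def test_cum_distractione_opens_background_gap(self, magnitude):
        bg = 20.0
        out = render_motif(_clean_band(bg=bg), "cum_distractione", magnitude)
        gap_cols = [
            c for c in range(out.shape[1]) if (out[17:26, c] <= bg + 1).all()
        ]
        runs = np.diff(gap_cols) if len(gap_cols) > 1 else []
        assert len(gap_cols) >= magnitude
        assert all(d == 1 for d in runs)

    def test_cum_contractione_brightens_overlap_zone(self):
        band = 150.0
        out = render_motif(_clean_band(band=band), "cum_contractione", 8)
        zone = out[17:26, 36:44]
        assert (zone > band).all()
        # zone width equals the magnitude
        brighter_cols = [
            c for c in range(out.shape[1]) if (out[17:26, c] > band + 1).any()
        ]
        assert len(brighter_cols) == 8

    def test_unknown_label_rejected(self):
        with pytest.raises(ConfigError):
            render_motif(_clean_band(), "ad_axim", 5)


class TestGenerateDataset:
    def test_manifest_and_annotation_bookkeeping(self, tmp_path):
        p = SimulationParams(seed=3, fractures_per_image=2)
        manifest = generate_dataset(p, 2, 3, tmp_path)
        assert len(manifest["images"]) == 5
        roles = [e["role"] for e in manifest["images"]]
        assert roles.count("positive") == 2 and roles.count("negative") == 3
        csv = (tmp_path / "annotations.csv").read_text().strip().splitlines()
        referenced = {line.split(",")[0] for line in csv[1:]}
        positives = {e["image_id"] for e in manifest["images"] if e["role"] == "positive"}
        assert referenced == positives

    def test_rerun_is_byte_identical(self, tmp_path):
        p = SimulationParams(seed=4)
        generate_dataset(p, 1, 1, tmp_path / "a")
        generate_dataset(p, 1, 1, tmp_path / "b")
        for name in ("annotations.csv", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        pngs = sorted(f.name for f in (tmp_path / "a").glob("*.png"))
        for name in pngs:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
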