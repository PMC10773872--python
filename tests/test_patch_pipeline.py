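"""Annotation rasterization, binarization, tissue filtering, class weights."""

import numpy as np
import pytest

from glandseg.patch_pipeline import (
    LABEL_CODES,
    LABEL_NAMES,
    PatchPair,
    binarize_mask,
    compute_class_weights,
    extract_patches,
    filter_patches,
    rasterize_annotations,
    read_geojson_annotations,
    tissue_ratio,
    write_geojson_annotations,
)


def _square(x0, y0, side):
    return [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]


class TestRasterize:
    def test_empty_polygon_list_gives_all_background(self):
        raster = rasterize_annotations([], (50, 50))
        assert np.all(raster == LABEL_CODES["Bg"])

    def test_pixel_exact_square(self):
        raster = rasterize_annotations(
            [("GP3", _square(20, 30, 10))], (100, 100)
        )
        assert int((raster == LABEL_CODES["GP3"]).sum()) == 100

    def test_later_polygons_overwrite_earlier(self):
        polys = [("GP4", _square(10, 10, 20)), ("N", _square(15, 15, 5))]
        raster = rasterize_annotations(polys, (50, 50))
        assert np.all(raster[16:19, 16:19] == LABEL_CODES["N"])
        assert raster[11, 11] == LABEL_CODES["GP4"]

    def test_unknown_label_lists_valid_names(self):
        with pytest.raises(ValueError, match="GP3"):
            rasterize_annotations([("Tumor", _square(0, 0, 5))], (10, 10))


class TestBinarize:
    def test_benign_only_maps_to_zero(self):
        raster = np.full((10, 10), LABEL_CODES["N"], dtype=np.uint8)
        assert np.all(binarize_mask(raster) == 0)

    def test_gp3_and_gp4_both_map_to_one(self):
        raster = np.full((10, 10), LABEL_CODES["GP3"], dtype=np.uint8)
        raster[5:] = LABEL_CODES["GP4"]
        assert np.all(binarize_mask(raster) == 1)

    def test_exact_pixel_count(self):
        raster = np.full((10, 10), LABEL_CODES["Bg"], dtype=np.uint8)
        raster.flat[:30] = LABEL_CODES["GP3"]
        assert int(binarize_mask(raster).sum()) == 30

    def test_all_other_labels_map_to_zero(self):
        for name in LABEL_NAMES:
            raster = np.full((4, 4), LABEL_CODES[name], dtype=np.uint8)
            expected = 1 if name in ("GP3", "GP4") else 0
            assert np.all(binarize_mask(raster) == expected)

    def test_invalid_code_raises(self):
        with pytest.raises(ValueError):
            binarize_mask(np.full((4, 4), 99))

    def test_idempotent_after_rasterize(self):
        polys = [("GP4", _square(5, 5, 10))]
        raster = rasterize_annotations(polys, (30, 30))
        once = binarize_mask(raster)
        np.testing.assert_array_equal(once, binarize_mask(raster))


class TestTissueRatio:
    def test_pure_white_is_zero(self):
        img = np.full((16, 16, 3), 255, dtype=np.uint8)
        assert tissue_ratio(img) == 0.0

    def test_pure_pink_is_one(self):
        img = np.full((16, 16, 3), (200, 150, 170), dtype=np.uint8)
        assert tissue_ratio(img) == 1.0

    def test_quarter_tissue(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        img[:32, :32] = (180, 120, 150)
        assert tissue_ratio(img) == pytest.approx(0.25)

    def test_empty_image_raises(self):
        with pytest.raises(ValueError):
            tissue_ratio(np.zeros((0, 0, 3), dtype=np.uint8))


class TestExtractPatches:
    def _slide(self, h, w):
        rng = np.random.default_rng(0)
        return (rng.integers(0, 255, (h, w, 3), dtype=np.uint8),
                rng.integers(0, 3, (h, w), dtype=np.uint8))

    def test_non_overlapping_grid(self):
        slide, labels = self._slide(512, 512)
        pairs = extract_patches(slide, labels, 256, 256)
        assert len(pairs) == 4
        assert {(p.grid_y, p.grid_x) for p in pairs} == {
            (0, 0), (0, 1), (1, 0), (1, 1)
        }

    def test_border_patches_dropped(self):
        slide, labels = self._slide(300, 300)
        assert len(extract_patches(slide, labels, 256, 256)) == 1

    def test_overlapping_stride(self):
        slide, labels = self._slide(512, 512)
        # floor((512-256)/128)+1 = 3 per axis
        assert len(extract_patches(slide, labels, 256, 128)) == 9

    def test_nonpositive_stride_raises(self):
        slide, labels = self._slide(64, 64)
        with pytest.raises(ValueError):
            extract_patches(slide, labels, 32, 0)

    def test_patch_content_matches_slide(self):
        slide, labels = self._slide(128, 128)
        pairs = extract_patches(slide, labels, 64, 64)
        p = [q for q in pairs if (q.grid_y, q.grid_x) == (1, 0)][0]
        np.testing.assert_array_equal(p.image, slide[64:128, 0:64])
        np.testing.assert_array_equal(p.mask, labels[64:128, 0:64])


class TestFilterPatches:
    def _pair(self, image, mask):
        return PatchPair(image=image, mask=mask)

    def test_all_background_patch_dropped(self):
        img = np.full((32, 32, 3), 250, dtype=np.uint8)
        mask = np.full((32, 32), LABEL_CODES["Bg"], dtype=np.uint8)
        assert filter_patches([self._pair(img, mask)]) == []

    def test_tissue_patch_kept(self):
        img = np.full((32, 32, 3), 250, dtype=np.uint8)
        img[:16] = (180, 120, 150)  # ratio 0.5
        mask = np.full((32, 32), LABEL_CODES["Bg"], dtype=np.uint8)
        mask.flat[:100] = LABEL_CODES["N"]
        kept = filter_patches([self._pair(img, mask)], min_tissue_ratio=0.25)
        assert len(kept) == 1

    def test_background_foreground_mixture_dropped(self):
        img = np.full((32, 32, 3), 250, dtype=np.uint8)
        img[:16] = (180, 120, 150)
        mask = np.full((32, 32), LABEL_CODES["Bg"], dtype=np.uint8)
        mask[:16] = LABEL_CODES["Fg"]
        assert filter_patches([self._pair(img, mask)]) == []

    def test_empty_input_gives_empty_output(self):
        assert filter_patches([]) == []


class TestClassWeights:
    def test_balanced_pixels_give_unit_weights(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[:5] = 1
        cw = compute_class_weights([mask])
        assert cw.as_tuple() == (1.0, 1.0)

    def test_inverse_frequency_formula(self):
        mask = np.zeros(1000, dtype=np.uint8)
        mask[:250] = 1  # N0=750, N1=250
        cw = compute_class_weights([mask])
        assert cw.w0 == pytest.approx(1000 / (2 * 750))
        assert cw.w1 == pytest.approx(2.0)

    def test_weight_ratio_identity(self):
        rng = np.random.default_rng(0)
        masks = [rng.integers(0, 2, (16, 16)) for _ in range(5)]
        cw = compute_class_weights(masks)
        n1 = sum(int(m.sum()) for m in masks)
        n0 = sum(m.size for m in masks) - n1
        assert cw.w1 / cw.w0 == pytest.approx(n0 / n1)

    def test_absent_class_raises_with_advice(self):
        with pytest.raises(ValueError, match="explicit"):
            compute_class_weights([np.zeros((8, 8), dtype=np.uint8)])


class TestGeoJSONRoundTrip:
    def test_polygons_survive_io(self, tmp_path):
        polys = [("GP3", _square(2, 3, 5)), ("N", _square(10, 10, 4))]
        path = tmp_path / "ann.geojson"
        write_geojson_annotations(polys, path)
        loaded = read_geojson_annotations(path)
        r1 = rasterize_annotations(polys, (30, 30))
        r2 = rasterize_annotations(loaded, (30, 30))
        np.testing.assert_array_equal(r1, r2)
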