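"""Unit + oracle-equivalence tests for the low-level image primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioslide.core_imaging import (
    BinaryMask,
    DegenerateInputError,
    ImageFormatError,
    LUMA_WEIGHTS,
    ParameterError,
    RasterImage,
    StructuringElement,
    bicubic_upscale,
    binarize,
    label_components,
    morphological_gradient,
    otsu_threshold,
    to_grayscale,
)
from oracles import (
    bf_bicubic_upscale,
    bf_dilate,
    bf_erode,
    bf_label,
    bf_otsu,
)


def _img(arr, **kw):
    return RasterImage(np.asarray(arr, dtype=np.uint8), **kw)


class TestToGrayscale:
    def test_single_channel_identity(self):
        arr = np.arange(12, dtype=np.uint8).reshape(3, 4)
        assert np.array_equal(to_grayscale(arr).pixels, arr)

    def test_equal_channels_give_constant(self):
        arr = np.full((4, 4, 3), 77, dtype=np.uint8)
        assert np.array_equal(to_grayscale(arr).pixels, np.full((4, 4), 77))

    def test_pure_red_uses_red_luminance_weight(self):
        arr = np.zeros((2, 2, 3), dtype=np.uint8)
        arr[..., 0] = 255
        expected = int(np.floor(LUMA_WEIGHTS[0] * 255 + 0.5))
        assert np.array_equal(to_grayscale(arr).pixels, np.full((2, 2), expected))

    def test_rejects_two_channel_input(self):
        with pytest.raises(ImageFormatError):
            to_grayscale(np.zeros((4, 4, 2), dtype=np.uint8))


class TestBicubicUpscale:
    def test_factor_one_is_identity(self):
        img = _img(np.random.default_rng(0).integers(0, 256, (5, 7)))
        assert np.array_equal(bicubic_upscale(img, 1).pixels, img.pixels)

    def test_constant_stays_constant_and_shape_scales(self):
        img = _img(np.full((3, 5), 131))
        out = bicubic_upscale(img, 4)
        assert out.shape == (12, 20)
        assert np.array_equal(out.pixels, np.full((12, 20), 131))

    def test_ramp_matches_bruteforce_kernel_and_corners(self):
        src = np.array([[0, 60], [120, 240]], dtype=np.uint8)
        out = bicubic_upscale(_img(src), 2).pixels
        expected = bf_bicubic_upscale(src, 2)
        assert np.array_equal(out, expected)
        # corner-aligned mapping keeps the source corners exact
        assert out[0, 0] == 0 and out[0, -1] == 60
        assert out[-1, 0] == 120 and out[-1, -1] == 240

    @pytest.mark.parametrize("seed", range(5))
    def test_random_images_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.integers(0, 256, (4, 5), dtype=np.uint8)
        factor = int(rng.integers(2, 5))
        assert np.array_equal(
            bicubic_upscale(_img(src), factor).pixels,
            bf_bicubic_upscale(src, factor),
        )

    def test_rejects_invalid_factor(self):
        with pytest.raises(ParameterError):
            bicubic_upscale(_img([[1, 2]]), 0)


class TestOtsu:
    def test_bimodal_half_and_half(self):
        px = np.array([[10] * 8, [200] * 8], dtype=np.uint8)
        t = otsu_threshold(_img(px))
        assert t == bf_otsu(px)
        mask = binarize(_img(px), t)
        assert np.array_equal(mask.pixels, (px == 200).astype(np.uint8))

    def test_extreme_values_split_perfectly(self):
        px = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        t = otsu_threshold(_img(px))
        assert np.array_equal(binarize(_img(px), t).pixels, (px == 255).astype(np.uint8))

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(_img(np.full((4, 4), 9)))

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_exhaustive_search_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        # mix of unimodal-noise and bimodal images
        if seed % 2:
            px = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        else:
            lo = rng.integers(0, 100, (12, 12))
            hi = rng.integers(120, 256, (12, 12))
            px = np.where(rng.uniform(size=(12, 12)) < 0.4, hi, lo).astype(np.uint8)
        assert otsu_threshold(_img(px)) == bf_otsu(px)


    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_skimage_on_bimodal_images(self, seed):
        """On clearly bimodal images both implementations pick a
        threshold in the same inter-mode plateau, so the resulting
        foreground masks coincide."""
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(seed)
        lo = rng.normal(40, 6, (16, 16))
        hi = rng.normal(200, 6, (16, 16))
        px = np.clip(np.where(rng.uniform(size=(16, 16)) < 0.5, hi, lo),
                     0, 255).astype(np.uint8)
        ours = otsu_threshold(_img(px))
        theirs = threshold_otsu(px)
        assert np.array_equal(px > ours, px > theirs)


class TestBinarize:
    def test_constant_zero_threshold_zero(self):
        assert not binarize(_img(np.zeros((3, 3))), 0).pixels.any()

    def test_all_above_threshold(self):
        assert binarize(_img(np.full((3, 3), 200)), 100).pixels.all()

    def test_threshold_is_strict(self):
        px = np.array([[50, 51]], dtype=np.uint8)
        assert list(binarize(_img(px), 50).pixels[0]) == [0, 1]

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ParameterError):
            binarize(_img([[0]]), 300)


class TestMorphologicalGradient:
    def test_empty_mask_stays_empty(self):
        assert not morphological_gradient(BinaryMask(np.zeros((5, 5)))).pixels.any()

    def test_full_mask_has_no_contour_with_reflect_border(self):
        assert not morphological_gradient(BinaryMask(np.ones((5, 5)))).pixels.any()

    def test_square_gives_ring_matching_bruteforce(self):
        mask = np.zeros((7, 7), dtype=np.uint8)
        mask[2:5, 2:5] = 1
        se = StructuringElement.square(3)
        out = morphological_gradient(BinaryMask(mask), se).pixels
        expected = bf_dilate(mask, se.footprint) - bf_erode(mask, se.footprint)
        assert np.array_equal(out, expected)
        assert out[3, 3] == 0          # interior removed
        assert out[2, 2] == 1          # boundary kept

    @pytest.mark.parametrize("seed", range(100))
    def test_random_masks_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        mask = (rng.uniform(size=(9, 11)) < 0.4).astype(np.uint8)
        se = StructuringElement.square(3)
        out = morphological_gradient(BinaryMask(mask), se).pixels
        dil = bf_dilate(mask, se.footprint)
        ero = bf_erode(mask, se.footprint)
        assert np.array_equal(out, dil - ero)
        # gradient is within the dilation and disjoint from the erosion
        assert np.all(out <= dil)
        assert not np.any(out & ero)

    def test_structuring_element_validation(self):
        with pytest.raises(ParameterError):
            StructuringElement(np.ones((2, 3), dtype=bool))
        with pytest.raises(ParameterError):
            StructuringElement(np.zeros((3, 3), dtype=bool))


class TestLabelComponents:
    def test_empty_mask_yields_no_objects(self):
        assert label_components(BinaryMask(np.zeros((4, 4)))) == []

    def test_two_disjoint_squares(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[0:2, 0:2] = 1
        mask[5:7, 5:7] = 1
        objs = label_components(BinaryMask(mask))
        assert len(objs) == 2
        assert all(o.area_px == 4 for o in objs)
        assert sorted(o.bbox for o in objs) == [(0, 0, 2, 2), (5, 5, 2, 2)]

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", range(50))
    def test_random_masks_match_floodfill(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        mask = (rng.uniform(size=(16, 16)) < 0.35).astype(np.uint8)
        objs = label_components(BinaryMask(mask), connectivity)
        got = sorted((o.area_px, o.bbox) for o in objs)
        assert got == bf_label(mask, connectivity)
        # component areas partition the foreground
        assert sum(o.area_px for o in objs) == int(mask.sum())


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(1, 30), st.integers(1, 30), st.integers(0, 2**16 - 1))
def test_raster_image_accepts_any_valid_16bit_grid(h, w, v):
    img = RasterImage(np.full((h, w), v, dtype=np.uint16), bitdepth=16)
    assert img.shape == (h, w)


def test_raster_image_rejects_out_of_range():
    with pytest.raises(ImageFormatError):
        RasterImage(np.array([[300]]), bitdepth=8)
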