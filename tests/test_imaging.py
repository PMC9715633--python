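import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alpinepheno import imaging, synth
from alpinepheno.errors import (
    DegenerateSeriesError,
    InvalidInputError,
    UndefinedIndexError,
)
from conftest import f1_score


def _rgb(arr):
    return imaging.RGBImage(pixels=np.asarray(arr, dtype=np.uint8))


class TestCanopyGreenness:
    def test_pure_green(self):
        img = _rgb(np.tile([0, 255, 0], (4, 4, 1)))
        assert imaging.canopy_greenness(img) == pytest.approx(1.0)

    def test_achromatic(self):
        for k in (1, 100, 255):
            img = _rgb(np.tile([k, k, k], (4, 4, 1)))
            assert imaging.canopy_greenness(img) == pytest.approx(1.0 / 3.0)

    def test_half_green_half_red(self):
        px = np.zeros((2, 2, 3), dtype=np.uint8)
        px[0, :, 1] = 255  # green row
        px[1, :, 0] = 255  # red row
        assert imaging.canopy_greenness(_rgb(px)) == pytest.approx(0.5)

    def test_all_black_roi_raises(self):
        with pytest.raises(UndefinedIndexError):
            imaging.canopy_greenness(_rgb(np.zeros((3, 3, 3))))

    def test_roi_mask_restricts(self):
        px = np.tile([0, 255, 0], (4, 4, 1)).astype(np.uint8)
        px[2:] = [255, 0, 0]
        roi = np.zeros((4, 4), dtype=bool)
        roi[:2] = True
        img = imaging.RGBImage(pixels=px, roi_mask=roi)
        assert imaging.canopy_greenness(img) == pytest.approx(1.0)

    def test_per_pixel_option(self):
        px = np.zeros((2, 1, 3), dtype=np.uint8)
        px[0, 0] = [0, 255, 0]
        px[1, 0] = [100, 100, 100]
        g = imaging.canopy_greenness(_rgb(px), per_pixel=True)
        assert g == pytest.approx((1.0 + 1.0 / 3.0) / 2.0)

    @given(scale=st.floats(min_value=0.1, max_value=3.0))
    @settings(max_examples=25, deadline=None)
    def test_channel_scaling_invariance(self, scale):
        rng = np.random.default_rng(0)
        base = rng.uniform(10, 80, (6, 6, 3))
        g0 = imaging.canopy_greenness(imaging.RGBImage(pixels=base))
        g1 = imaging.canopy_greenness(imaging.RGBImage(pixels=base * scale))
        assert g1 == pytest.approx(g0, abs=1e-12)


class TestDestripe:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 50.0)
        np.testing.assert_allclose(imaging.destripe(img), img, atol=1e-9)

    def test_stripe_rms_reduced_5x(self, clean_soil):
        stripes = 20.0 * np.random.default_rng(1).standard_normal(512)[None, :]
        striped = clean_soil + stripes
        out = imaging.destripe(striped)
        before = np.sqrt(np.mean((striped - clean_soil) ** 2))
        after = np.sqrt(np.mean((out - clean_soil) ** 2))
        assert before / after >= 5.0

    def test_stripe_free_changed_below_1pct_of_range(self, clean_soil):
        out = imaging.destripe(clean_soil)
        rms = np.sqrt(np.mean((out - clean_soil) ** 2))
        assert rms < 0.01 * 255.0

    def test_idempotent_within_1pct(self, clean_soil):
        striped = clean_soil + 20.0 * np.random.default_rng(2).standard_normal(512)[None, :]
        once = imaging.destripe(striped)
        twice = imaging.destripe(once)
        rms = np.sqrt(np.mean((twice - once) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(once**2))

    def test_too_narrow_rejected(self):
        with pytest.raises(InvalidInputError):
            imaging.destripe(np.zeros((32, 8)))


class TestNormalize:
    def test_fixed_point(self):
        rng = np.random.default_rng(3)
        img = rng.normal(100, 20, (64, 64))
        once = imaging.normalize(img)
        twice = imaging.normalize(once)
        np.testing.assert_allclose(twice, once, atol=1e-6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        img = rng.normal(0, 1, (32, 32))
        a = imaging.normalize(img)
        b = imaging.normalize(3.7 * img + 42.0)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_monotone_non_strict(self):
        rng = np.random.default_rng(5)
        img = rng.normal(0, 1, (16, 16))
        out = imaging.normalize(img)
        fi, fo = img.ravel(), out.ravel()
        order = np.argsort(fi)
        assert np.all(np.diff(fo[order]) >= -1e-12)

    def test_target_moments(self):
        img = np.random.default_rng(6).normal(5, 2, (64, 64))
        out = imaging.normalize(img, target_mean=0.5, target_sd=0.15)
        assert out.mean() == pytest.approx(0.5, abs=1e-9)
        assert out.std() == pytest.approx(0.15, abs=1e-9)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateSeriesError):
            imaging.normalize(np.full((16, 16), 7.0))


class TestAlignment:
    def test_duplicate_pair_zero_shift(self, clean_soil):
        stack = imaging.RhizotronStack(images=[clean_soil, clean_soil.copy()], doys=[0, 1])
        out = imaging.align_stack(stack)
        assert out.shifts == [(0, 0), (0, 0)]

    def test_programmed_shifts_recovered_exactly(self, rhizo_stack):
        stack, _, shifts = rhizo_stack
        des = [imaging.destripe(im) for im in stack.images]
        out = imaging.align_stack(imaging.RhizotronStack(images=des, doys=stack.doys))
        assert out.shifts == shifts

    def test_pure_noise_flagged_low_confidence(self):
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(2)
        a, b = rng1.normal(0, 1, (128, 128)), rng2.normal(0, 1, (128, 128))
        stack = imaging.RhizotronStack(images=[a, b], doys=[0, 1])
        with pytest.warns(UserWarning, match="below floor"):
            out = imaging.align_stack(stack, peak_floor=0.2)
        assert out.shifts[1] == (0, 0)

    def test_single_image_rejected(self, clean_soil):
        with pytest.raises(InvalidInputError):
            imaging.align_stack(imaging.RhizotronStack(images=[clean_soil], doys=[0]))

    def test_translation_conserves_interior_area(self):
        rng = np.random.default_rng(7)
        mask = rng.random((100, 100)) > 0.7
        shifted = imaging.translate(mask.astype(float), 4, -3) > 0.5
        # changes bounded by perimeter x |shift|
        lost = abs(int(mask.sum()) - int(shifted.sum()))
        assert lost <= (2 * (100 + 100)) * 4


class TestTile:
    def test_grid_16_tiles_at_full_scan_size(self):
        img = np.zeros((8784, 10200), dtype=np.uint8)
        tiles = imaging.tile(img, 4, 4)
        assert len(tiles) == 16
        assert all(t.shape == (2196, 2550) for t in tiles)

    def test_identity_grid(self):
        img = np.arange(12.0).reshape(3, 4)
        (only,) = imaging.tile(img, 1, 1)
        np.testing.assert_array_equal(only, img)

    def test_pixel_sum_conserved(self):
        rng = np.random.default_rng(8)
        img = rng.random((60, 80))
        tiles = imaging.tile(img, 4, 3)
        assert sum(t.sum() for t in tiles) == pytest.approx(img.sum())

    def test_row_major_reassembly(self):
        img = np.arange(64.0).reshape(8, 8)
        tiles = imaging.tile(img, 2, 2)
        top = np.hstack(tiles[:2])
        bottom = np.hstack(tiles[2:])
        np.testing.assert_array_equal(np.vstack([top, bottom]), img)

    def test_grid_larger_than_image_rejected(self):
        with pytest.raises(InvalidInputError):
            imaging.tile(np.zeros((4, 4)), 8, 1)

    def test_large_remainder_rejected(self):
        with pytest.raises(InvalidInputError):
            imaging.tile(np.zeros((10, 10)), 4, 1)


class TestSegmentation:
    def test_blank_soil_below_half_percent(self, clean_soil):
        mask = imaging.segment_roots(imaging.normalize(clean_soil))
        assert mask.mean() < 0.005

    def test_single_stroke_f1(self):
        stack, _ = synth.gen_rhizotron_stack(1, (256, 256), root_schedule=[2.0], seed=3)
        mask = imaging.segment_roots(imaging.normalize(stack.images[0]))
        assert f1_score(mask, stack.masks[0]) >= 0.80

    def test_rotation_symmetry(self):
        stack, _ = synth.gen_rhizotron_stack(1, (128, 128), root_schedule=[1.0], seed=4)
        img = imaging.normalize(stack.images[0])
        a = imaging.segment_roots(np.rot90(img, 2))
        b = np.rot90(imaging.segment_roots(img), 2)
        np.testing.assert_array_equal(a, b)

    def test_deterministic(self, clean_soil):
        img = imaging.normalize(clean_soil)
        np.testing.assert_array_equal(
            imaging.segment_roots(img), imaging.segment_roots(img)
        )


class TestRootArea:
    def test_empty_mask(self):
        per_cm2, mm2 = imaging.root_area(np.zeros((10, 10), dtype=bool), 1200)
        assert per_cm2 == 0.0 and mm2 == 0.0

    def test_closed_form_at_scan_geometry(self):
        mask = np.zeros((2196, 2550), dtype=bool)
        mask.ravel()[:10_000] = True
        per_cm2, mm2 = imaging.root_area(mask, 1200)
        px = (25.4 / 1200) ** 2
        assert mm2 == pytest.approx(10_000 * px, abs=1e-9)
        assert per_cm2 == pytest.approx(10_000 * px / (2196 * 2550 * px / 100), abs=1e-9)
        assert mm2 == pytest.approx(4.480, abs=5e-4)
        assert per_cm2 == pytest.approx(0.1786, abs=5e-5)

    def test_linearity(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[:10] = True
        a1, m1 = imaging.root_area(mask, 600)
        mask[10:20] = True
        a2, m2 = imaging.root_area(mask, 600)
        assert a2 == pytest.approx(2 * a1) and m2 == pytest.approx(2 * m1)

    def test_bad_dpi(self):
        with pytest.raises(InvalidInputError):
            imaging.root_area(np.zeros((4, 4), dtype=bool), 0)


class TestRootDiameters:
    def test_bar_width_10px(self):
        mask = np.zeros((60, 200), dtype=bool)
        mask[25:35, 20:180] = True  # 10 px wide horizontal bar
        d = imaging.root_diameters(mask, 1200)
        assert d.mean_mm == pytest.approx(10 * 25.4 / 1200, rel=0.05)

    def test_single_pixel_line(self):
        mask = np.zeros((20, 50), dtype=bool)
        mask[10, 5:45] = True
        d = imaging.root_diameters(mask, 1200)
        # medial-axis distance of a 1-px line is 1 px => diameter ~ 2 px equiv
        assert d.max_mm <= 2 * 25.4 / 1200 + 1e-9

    def test_max_bounded_by_diagonal(self):
        rng = np.random.default_rng(9)
        mask = rng.random((64, 64)) > 0.3
        d = imaging.root_diameters(mask, 300)
        diag = np.hypot(64, 64) * 25.4 / 300
        assert d.max_mm <= diag

    def test_empty_mask_sentinel(self):
        d = imaging.root_diameters(np.zeros((8, 8), dtype=bool), 1200)
        assert d.empty and np.isnan(d.mean_mm)
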