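import numpy as np
import pytest
from skimage.exposure import match_histograms

from celldet import (
    AugmentationSpec,
    Box,
    HistogramSpecifier,
    ReferenceHistogram,
    augment,
    default_reference_histogram,
    fit_reference_histogram,
    histogram_specify,
    make_tile_grid,
    positive_fraction,
    select_for_augmentation,
)
from celldet.augnorm import _channels, transform_box


def ks_distance(values: np.ndarray, ref: ReferenceHistogram, channel: int) -> float:
    ecdf = np.searchsorted(np.sort(values.ravel()), ref.levels, side="right") / values.size
    return float(np.abs(ecdf - ref.cdfs[channel]).max())


class TestPositiveFraction:
    def test_full_containment(self):
        assert positive_fraction(Box(10, 10, 20, 20), [Box(0, 0, 50, 50)]) == 1.0

    def test_disjoint(self):
        assert positive_fraction(Box(0, 0, 10, 10), [Box(50, 50, 60, 60)]) == 0.0

    def test_half_strip(self):
        patch = Box(0, 0, 100, 100)
        assert positive_fraction(patch, [Box(0, 0, 50, 100)]) == pytest.approx(0.5)

    def test_overlapping_annotations_not_double_counted(self):
        patch = Box(0, 0, 100, 100)
        anns = [Box(0, 0, 50, 100), Box(25, 0, 50, 100)]
        assert positive_fraction(patch, anns) == pytest.approx(0.5)

    def test_monotone_under_annotation_growth(self, rng):
        patch = Box(20, 20, 80, 80)
        anns = []
        prev = 0.0
        for _ in range(10):
            x, y = rng.uniform(0, 80, 2)
            anns.append(Box(x, y, x + 15, y + 15))
            cur = positive_fraction(patch, anns)
            assert cur >= prev - 1e-12
            prev = cur


class TestSelection:
    def test_no_annotations_selects_nothing(self):
        grid = make_tile_grid(100, 100, 50)
        assert not any(s.selected for s in select_for_augmentation(grid, []))

    def test_annotation_spanning_two_tiles_selects_both(self):
        grid = make_tile_grid(100, 100, 50)
        sels = select_for_augmentation(grid, [Box(40, 10, 60, 30)])
        assert [s.selected for s in sels] == [True, True, False, False]

    def test_selected_iff_positive_fraction(self, rng):
        grid = make_tile_grid(200, 200, 50)
        anns = [Box(x, y, x + 20, y + 20) for x, y in rng.uniform(0, 180, (5, 2))]
        for s in select_for_augmentation(grid, anns):
            assert s.selected == (s.positive_fraction > 0)


class TestAugment:
    def test_identity_spec_single_unchanged_copy(self, rng):
        img = rng.random((32, 32, 3))
        spec = AugmentationSpec(
            rotation_angles=(), flips=(), contrast_range=0, saturation_range=0,
            brightness_range=0,
        )
        copies = augment(img, spec)
        assert len(copies) == 1
        np.testing.assert_array_equal(copies[0], img)

    def test_default_spec_copy_count(self, rng):
        img = rng.random((32, 32, 3))
        spec = AugmentationSpec()
        copies = augment(img, spec)
        assert len(copies) == spec.n_copies == 8 + 2 + spec.n_jitter

    def test_same_seed_bit_identical(self, rng):
        img = rng.random((32, 32, 3))
        a = augment(img, AugmentationSpec(seed=7))
        b = augment(img, AugmentationSpec(seed=7))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_outputs_clipped_to_unit_range(self, rng):
        img = rng.random((32, 32, 3))
        for copy in augment(img, AugmentationSpec(seed=3)):
            assert copy.min() >= 0 and copy.max() <= 1

    def test_empty_image_is_error(self):
        with pytest.raises(ValueError):
            augment(np.empty((0, 0, 3)), AugmentationSpec())

    def test_ranges_beyond_printed_limits_rejected(self):
        with pytest.raises(ValueError):
            AugmentationSpec(contrast_range=0.3)
        with pytest.raises(ValueError):
            AugmentationSpec(brightness_range=0.2)


class TestTransformBox:
    def test_right_angle_matches_rot90_of_mask(self):
        # blob occupying a known box; rotate mask and box the same way
        img = np.zeros((40, 40))
        box = Box(5, 10, 15, 22)
        img[int(box.y_min):int(box.y_max), int(box.x_min):int(box.x_max)] = 1
        rot = np.rot90(img, k=1)
        tb = transform_box(box, 40, 40, angle=90)
        ys, xs = np.nonzero(rot)
        assert tb == Box(float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))

    def test_flip_horizontal(self):
        tb = transform_box(Box(5, 10, 15, 22), 40, 40, flip="horizontal")
        assert tb == Box(25, 10, 35, 22)

    @pytest.mark.parametrize("angle", [5, 25, 90, 180, 270])
    def test_rotated_corners_stay_within_patch(self, angle, rng):
        for _ in range(20):
            x, y = rng.uniform(5, 20, 2)
            box = Box(x, y, x + rng.uniform(2, 10), y + rng.uniform(2, 10))
            tb = transform_box(box, 40, 40, angle=angle)
            assert tb is not None
            assert 0 <= tb.x_min < tb.x_max <= 40
            assert 0 <= tb.y_min < tb.y_max <= 40


class TestReferenceHistogram:
    def test_uniform_gray_image_gives_step_cdf(self):
        ref = fit_reference_histogram([np.full((8, 8), 0.5)])
        assert ref.cdfs.shape[0] == 1
        assert np.interp(0.49, ref.levels, ref.cdfs[0]) == pytest.approx(0.0, abs=0.01)
        assert np.interp(0.51, ref.levels, ref.cdfs[0]) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_ranges_pool_into_two_rises(self):
        lo = np.full((2, 2), 0.1)
        hi = np.full((2, 2), 0.9)
        ref = fit_reference_histogram([lo, hi])
        mid = np.interp(0.5, ref.levels, ref.cdfs[0])
        assert mid == pytest.approx(0.5, abs=0.01)

    def test_cdf_ends_at_one(self, rng):
        ref = fit_reference_histogram([rng.random((16, 16, 3))])
        assert np.allclose(ref.cdfs[:, -1], 1.0)

    def test_text_roundtrip(self, rng):
        ref = fit_reference_histogram([rng.random((16, 16, 3))])
        back = ReferenceHistogram.from_text(ref.to_text())
        np.testing.assert_allclose(back.levels, ref.levels, atol=1e-9)
        np.testing.assert_allclose(back.cdfs, ref.cdfs, atol=1e-9)

    def test_invalid_cdf_rejected(self):
        with pytest.raises(ValueError):
            ReferenceHistogram(levels=np.array([0, 1.0]), cdfs=np.array([[0.5, 0.4]]))

    def test_empty_fit_is_error(self):
        with pytest.raises(ValueError):
            fit_reference_histogram([])


class TestHistogramSpecification:
    def test_self_specification_identity_up_to_quantization(self, rng):
        img = rng.random((64, 64, 3))
        out = histogram_specify(img, fit_reference_histogram([img]))
        assert np.abs(out - img).max() < 2 / 256

    def test_constant_image_maps_to_reference_median(self):
        ref = default_reference_histogram(n_channels=1)
        out = histogram_specify(np.full((8, 8), 0.3), ref)
        assert np.allclose(out, ref.median(0))

    def test_uniform_source_to_uniform_reference_preserves_ramp(self):
        ramp = np.linspace(0, 1, 4096).reshape(64, 64)
        levels = np.linspace(0, 1, 256)
        uniform_ref = ReferenceHistogram(levels=levels, cdfs=levels[None, :])
        out = histogram_specify(ramp, uniform_ref)
        assert np.abs(out - ramp).max() < 0.01

    def test_ks_distance_to_reference_small_on_noise(self, rng):
        ref = default_reference_histogram()
        img = rng.random((128, 128, 3))
        out = histogram_specify(img, ref)
        for c in range(3):
            assert ks_distance(_channels(out)[c], ref, c) <= 0.02

    def test_agrees_with_skimage_match_histograms(self, rng):
        """Independent cross-check: specifying to a CDF fitted from a single
        reference image must agree with direct image-to-image histogram
        matching."""
        src = rng.random((64, 64))
        ref_img = rng.beta(2, 5, (64, 64))
        ours = histogram_specify(src, fit_reference_histogram([ref_img]))
        theirs = match_histograms(src, ref_img)
        assert np.abs(ours - theirs).max() < 2 / 256

    def test_channel_mismatch_is_error(self, rng):
        with pytest.raises(ValueError):
            histogram_specify(rng.random((8, 8)), default_reference_histogram(3))


class TestHistogramSpecifier:
    def test_fit_transform_roundtrip(self, rng):
        imgs = [rng.random((32, 32, 3)) for _ in range(3)]
        hs = HistogramSpecifier().fit(imgs)
        (out,) = hs.transform(imgs[0])
        assert out.shape == imgs[0].shape

    def test_default_reference_when_unfitted_input(self):
        hs = HistogramSpecifier().fit()
        np.testing.assert_array_equal(
            hs.reference_.cdfs, default_reference_histogram().cdfs
        )

    def test_transform_before_fit_is_error(self, rng):
        with pytest.raises(RuntimeError):
            HistogramSpecifier().transform(rng.random((8, 8, 3)))
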