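"""Preprocessing: standardization, tiling bijection, Gaussian targets,
biased crop sampling."""

import numpy as np
import pytest

from jawnet.config import GeometryConfig, tiny_config
from jawnet.phantom import Lesion, generate_sample, tiny_spec
from jawnet.preprocess import (gaussian_heatmap_target, preprocess_image,
                               sample_training_crop, split_into_patches,
                               standardize, stitch_patches)


@pytest.fixture(scope="module")
def geo():
    return tiny_config().geometry


def _lesion(mask):
    from jawnet.phantom import tight_bbox
    return Lesion(mask=mask, bbox=tight_bbox(mask), cls="DC")


class TestStandardization:
    def test_constant_image_maps_to_zeros(self, geo):
        with pytest.warns(UserWarning, match="constant"):
            out = preprocess_image(np.full((150, 300), 0.5, np.float32), geo)
        np.testing.assert_array_equal(out, 0.0)

    def test_output_has_zero_mean_unit_std(self, geo, rng):
        out = preprocess_image(rng.random((160, 320)).astype(np.float32), geo)
        assert abs(out.mean()) < 1e-5 and abs(out.std() - 1) < 1e-5

    def test_idempotent_up_to_epsilon(self, rng):
        x = standardize(rng.random((40, 40)).astype(np.float32))
        np.testing.assert_allclose(standardize(x), x, atol=1e-5)

    def test_crop_box_matches_bruteforce_threshold_scan(self, geo):
        """Content occupying the central 80%: the crop equals the tight box
        of the thresholded content (plus the 1% padding)."""
        from skimage.filters import threshold_otsu
        img = np.zeros((150, 300), np.float32)
        img[15:135, 30:270] = 0.8
        _, box = preprocess_image(img, geo, return_box=True)
        th = threshold_otsu(img)
        ys, xs = np.nonzero(img > th)
        tight = (xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)
        pad_x, pad_y = round(0.01 * 300), round(0.01 * 150)
        expect = (max(0, tight[0] - pad_x), max(0, tight[1] - pad_y),
                  min(300, tight[2] + pad_x), min(150, tight[3] + pad_y))
        assert box == expect


class TestPatchTiling:
    def test_reference_grid_geometry(self):
        geo = GeometryConfig().validate()
        img = np.arange(750 * 1500, dtype=np.float32).reshape(750, 1500)
        grid = split_into_patches(img, geo)
        assert len(grid) == 8
        assert all(p.shape == (375, 375) for p in grid.patches)
        # row-major: patch 1 is the second column of the top row
        np.testing.assert_array_equal(grid.patches[1], img[0:375, 375:750])

    def test_roundtrip_bit_exact(self, geo, rng):
        img = rng.random((150, 300)).astype(np.float32)
        grid = split_into_patches(img, geo)
        np.testing.assert_array_equal(stitch_patches(grid), img)

    def test_single_patch_grid_is_identity(self, rng):
        geo = GeometryConfig(raw_size=(64, 64), working_size=(64, 64),
                             grid=(1, 1), patch_size=64, seg_size=(32, 32),
                             heatmap_variance=2.0).validate()
        img = rng.random((64, 64)).astype(np.float32)
        grid = split_into_patches(img, geo)
        assert len(grid) == 1
        np.testing.assert_array_equal(grid.patches[0], img)

    def test_wrong_size_rejected(self, geo):
        with pytest.raises(ValueError):
            split_into_patches(np.zeros((100, 100), np.float32), geo)


class TestGaussianTarget:
    def test_no_lesions_gives_zero_map(self, geo):
        t = gaussian_heatmap_target([], geo)
        assert t.shape == (75, 150) and not t.any()

    def test_reference_variance_formula(self):
        """Peak 1 at the centre; exp(-d^2/(2*50)) at distance d (sigma^2=50)."""
        geo = GeometryConfig().validate()
        mask = np.zeros((750, 1500), bool)
        mask[370:380, 700:710] = True          # centre (705, 375) -> seg (352, 187)
        t = gaussian_heatmap_target([_lesion(mask)], geo)
        cy, cx = 188, 352                      # rounded centre in seg coords
        assert t.max() == pytest.approx(1.0)
        assert t[cy, cx] == pytest.approx(1.0)
        for d in (3, 7, 12):
            assert t[cy, cx + d] == pytest.approx(np.exp(-d * d / 100.0), rel=1e-5)

    def test_multiple_lesions_combine_by_pointwise_max(self, geo):
        m1 = np.zeros((150, 300), bool)
        m2 = np.zeros((150, 300), bool)
        m1[60:80, 90:110] = True
        m2[60:80, 104:124] = True
        combined = gaussian_heatmap_target([_lesion(m1), _lesion(m2)], geo)
        f1 = gaussian_heatmap_target([_lesion(m1)], geo)
        f2 = gaussian_heatmap_target([_lesion(m2)], geo)
        np.testing.assert_array_equal(combined, np.maximum(f1, f2))

    def test_values_bounded_and_peak_iff_lesion(self, geo):
        rng = np.random.default_rng(0)
        s = generate_sample(tiny_spec(), "AB", rng)
        t = gaussian_heatmap_target(s.lesions, geo)
        assert 0.0 <= t.min() and t.max() == pytest.approx(1.0)


class TestCropSampler:
    def test_normal_sample_uniform_and_zero_target(self, geo, rng):
        img = rng.random((150, 300)).astype(np.float32)
        crop, target, _ = sample_training_crop(img, [], 75, geo, rng)
        assert crop.shape == (75, 75) and target.shape == (37, 37)
        assert not target.any()

    def test_crop_target_is_window_of_full_heatmap(self, geo, rng):
        s = generate_sample(tiny_spec(seed=4), "DC", np.random.default_rng(4))
        full = gaussian_heatmap_target(s.lesions, geo)
        crop, target, (x0, y0) = sample_training_crop(s.image, s.lesions, 75,
                                                      geo, rng)
        np.testing.assert_array_equal(
            target, full[y0 // 2:y0 // 2 + 37, x0 // 2:x0 // 2 + 37])
        np.testing.assert_array_equal(crop, s.image[y0:y0 + 75, x0:x0 + 75])

    def test_overlap_frequency_three_to_one(self, geo):
        """Binomial oracle: lesion-overlapping crops 3x as often as free
        ones => frequency 0.75 within 3 sigma over 2000 draws."""
        rng = np.random.default_rng(9)
        s = generate_sample(tiny_spec(seed=9), "OKC", rng)
        n, hits = 2000, 0
        bbox = s.lesions[0].bbox
        for _ in range(n):
            _, _, (x0, y0) = sample_training_crop(s.image, s.lesions, 75, geo, rng)
            if (x0 < bbox[2] and x0 + 75 > bbox[0]
                    and y0 < bbox[3] and y0 + 75 > bbox[1]):
                hits += 1
        sigma = np.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) <= 3 * sigma

    def test_oversized_crop_rejected(self, geo, rng):
        with pytest.raises(ValueError):
            sample_training_crop(np.zeros((150, 300), np.float32), [], 200,
                                 geo, rng)
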