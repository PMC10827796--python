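"""LesionMix pixel-provenance contract, Mixup/CutMix baselines, offline
balancing, and online augmentation statistics."""

import numpy as np
import pytest
from scipy import ndimage

from jawnet.augment import (balance_offline, cutmix, lesion_mix, mixup,
                            online_augment)
from jawnet.config import LesionMixParams
from jawnet.phantom import generate_dataset, generate_sample, tiny_spec


@pytest.fixture(scope="module")
def pair():
    rng = np.random.default_rng(21)
    donor = generate_sample(tiny_spec(seed=21), "AB", rng)
    recipient = generate_sample(tiny_spec(seed=21), "Normal", rng)
    return donor, recipient


class TestLesionMix:
    def test_hard_paste_matches_compositing_oracle(self, pair, rng):
        """feather_radius=0: out = recipient*(1-mask) + donor*mask, exactly."""
        donor, recipient = pair
        out = lesion_mix(donor, recipient, LesionMixParams(feather_radius=0), rng)
        m = donor.lesions[0].mask
        expected = recipient.image * (~m) + donor.image * m
        np.testing.assert_array_equal(out.image, expected.astype(np.float32))
        assert out.label == "AB" and out.provenance == "augmented"

    def test_feathered_pixel_provenance_trichotomy(self, pair, rng):
        """Outside the r-dilated mask: recipient, exactly.  Inside the
        r-eroded mask: donor, exactly.  Feather band: monotone blend."""
        donor, recipient = pair
        r = 2
        out = lesion_mix(donor, recipient, LesionMixParams(feather_radius=r), rng)
        m = donor.lesions[0].mask
        d_in = ndimage.distance_transform_edt(m)
        d_out = ndimage.distance_transform_edt(~m)
        outside = d_out > r
        inside = d_in > r
        np.testing.assert_array_equal(out.image[outside], recipient.image[outside])
        np.testing.assert_array_equal(out.image[inside], donor.image[inside])
        band = ~outside & ~inside
        lo = np.minimum(recipient.image, donor.image) - 1e-6
        hi = np.maximum(recipient.image, donor.image) + 1e-6
        assert np.all(out.image[band] >= lo[band])
        assert np.all(out.image[band] <= hi[band])

    def test_mask_and_label_copied_from_donor(self, pair, rng):
        donor, recipient = pair
        out = lesion_mix(donor, recipient, LesionMixParams(), rng)
        np.testing.assert_array_equal(out.lesions[0].mask, donor.lesions[0].mask)
        assert out.lesions[0].bbox == donor.lesions[0].bbox

    def test_preserves_recipient_statistics_outside_lesion(self, pair, rng):
        donor, recipient = pair
        r = 2
        out = lesion_mix(donor, recipient, LesionMixParams(feather_radius=r), rng)
        outside = ndimage.distance_transform_edt(~donor.lesions[0].mask) > r
        assert out.image[outside].mean() == recipient.image[outside].mean()

    def test_degenerate_donor_rejected(self, pair, rng):
        donor, recipient = pair
        with pytest.raises(ValueError):
            lesion_mix(recipient, recipient, LesionMixParams(), rng)  # no lesion
        with pytest.raises(ValueError):
            lesion_mix(donor, donor, LesionMixParams(), rng)  # recipient abnormal


class TestBaselines:
    def test_mixup_identities_and_oracle(self, pair, rng):
        donor, recipient = pair
        np.testing.assert_array_equal(mixup(donor, recipient, 1.0), donor.image)
        a = np.zeros((4, 4), np.float32)
        b = np.ones((4, 4), np.float32)
        np.testing.assert_allclose(mixup(a, b, 0.5), 0.5)
        lam = 0.3
        got = mixup(donor, recipient, lam)
        brute = np.empty_like(got)
        for i in range(got.shape[0]):
            for j in range(got.shape[1]):
                brute[i, j] = np.float32(lam) * donor.image[i, j] \
                    + np.float32(1 - lam) * recipient.image[i, j]
        np.testing.assert_allclose(got, brute, atol=1e-7)
        with pytest.raises(ValueError):
            mixup(donor, recipient, 1.2)

    def test_cutmix_whole_image_box_returns_a(self, pair, rng):
        donor, recipient = pair
        out = cutmix(donor, recipient, rng, box=(0, 0, 300, 150))
        np.testing.assert_array_equal(out, donor.image)

    def test_cutmix_quarter_area_pixel_count(self, rng):
        a = np.zeros((100, 100), np.float32)
        b = np.ones((100, 100), np.float32)
        out = cutmix(a, b, rng, box=(10, 20, 60, 70))
        assert int((out != b).sum()) == 50 * 50   # exactly the box area

    def test_cutmix_seeded_reproducible(self, pair):
        donor, recipient = pair
        o1 = cutmix(donor, recipient, np.random.default_rng(5))
        o2 = cutmix(donor, recipient, np.random.default_rng(5))
        np.testing.assert_array_equal(o1, o2)


class TestBalanceOffline:
    def test_published_oversampling_targets(self):
        """75/97/193/200 balanced to 200/194/193/200."""
        ds = generate_dataset(tiny_spec(
            seed=2, counts={"AB": 3, "OKC": 4, "DC": 8, "Normal": 8}))
        # scaled-down shape of the published counts and targets
        targets = {"AB": 8, "OKC": 8, "DC": 8, "Normal": 8}
        out = balance_offline(ds, targets, np.random.default_rng(0))
        from collections import Counter
        assert Counter(s.label for s in out) == targets
        dupes = [s for s in out if s.meta.get("duplicate")]
        assert len(dupes) == sum(targets.values()) - len(ds)

    def test_identity_when_targets_equal_current(self):
        ds = generate_dataset(tiny_spec(seed=3))
        out = balance_offline(ds, {"AB": 2, "OKC": 2, "DC": 2, "Normal": 2},
                              np.random.default_rng(0))
        assert len(out) == len(ds)

    def test_target_below_current_rejected(self):
        ds = generate_dataset(tiny_spec(seed=3))
        with pytest.raises(ValueError):
            balance_offline(ds, {"AB": 1}, np.random.default_rng(0))


class TestOnlineAugment:
    def test_identity_under_degenerate_parameters(self, pair):
        donor, _ = pair
        out = online_augment(donor, np.random.default_rng(0), p_flip=0.0,
                             max_rotation=0.0, brightness=0.0, contrast=0.0,
                             saturation=0.0, hue=0.0)
        np.testing.assert_array_equal(out.image, donor.image)
        np.testing.assert_array_equal(out.lesions[0].mask, donor.lesions[0].mask)

    def test_double_flip_mask_consistency(self, pair):
        donor, _ = pair
        out = online_augment(donor, np.random.default_rng(0), p_flip=1.0,
                             max_rotation=0.0, brightness=0.0, contrast=0.0,
                             saturation=0.0, hue=0.0)
        np.testing.assert_array_equal(out.lesions[0].mask,
                                      donor.lesions[0].mask[::-1, ::-1])
        np.testing.assert_array_equal(out.image, donor.image[::-1, ::-1])

    def test_flip_frequency_within_3_sigma(self):
        """Binomial oracle: the horizontal flip fires with p = 0.5."""
        from jawnet.phantom import RadiographSample
        # asymmetric marker image so every flip state is distinguishable
        img = np.zeros((8, 8), np.float32)
        img[0, 0] = 1.0
        s = RadiographSample(image=img, label="Normal")
        rng = np.random.default_rng(17)
        n, h_flips = 2000, 0
        for _ in range(n):
            out = online_augment(s, rng, max_rotation=0.0, brightness=0.0,
                                 contrast=0.0, saturation=0.0, hue=0.0)
            if np.array_equal(out.image, img[:, ::-1]) \
                    or np.array_equal(out.image, img[::-1, ::-1]):
                h_flips += 1
        sigma = np.sqrt(0.25 / n)
        assert abs(h_flips / n - 0.5) <= 3 * sigma

    def test_rotation_keeps_masks_consistent(self, pair):
        donor, _ = pair
        out = online_augment(donor, np.random.default_rng(1), p_flip=0.0,
                             brightness=0.0, contrast=0.0, saturation=0.0,
                             hue=0.0)
        assert out.lesions and out.lesions[0].mask.any()
        out.validate()
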