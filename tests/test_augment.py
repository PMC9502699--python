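"""Augmentation operator semantics and the cumulative-level contract."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ptxmode.augment import (AugmentationError, AugmentationPlan,
                             build_training_set, emd_64bin, flip,
                             histogram_counts, histogram_match, jitter, zoom)
from ptxmode.usim import MmodeSpec, PHANTOM_DOMAIN, SWINE_DOMAIN, generate_mmode


def specification_oracle(image, reference, bins=64):
    """Classical sort-based histogram specification, independent of the
    implementation under test: each pixel's empirical quantile (<= CDF) is
    mapped through the inverse reference CDF onto bin centers."""
    centers = (np.arange(bins) + 0.5) / bins
    img = image.ravel()
    ref_bins = np.minimum((reference.ravel() * bins).astype(int), bins - 1)
    ref_sorted = np.sort(centers[ref_bins])
    out = np.empty_like(img)
    for i, v in enumerate(img):
        q = np.mean(img <= v)
        k = np.searchsorted(np.arange(1, ref_sorted.size + 1) / ref_sorted.size,
                            q - 1e-12)
        out[i] = ref_sorted[min(k, ref_sorted.size - 1)]
    return out.reshape(image.shape)


class TestFlip:
    def test_involution(self, rng):
        img = rng.random((9, 7))
        for axis in ("x", "y"):
            np.testing.assert_array_equal(flip(flip(img, axis), axis), img)

    def test_2x2_column_reversal(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(flip(img, "x"),
                                      np.array([[2.0, 1.0], [4.0, 3.0]]))
        np.testing.assert_array_equal(flip(img, "y"),
                                      np.array([[3.0, 4.0], [1.0, 2.0]]))

    def test_symmetric_image_unchanged(self):
        img = np.array([[1.0, 2.0, 1.0], [0.0, 5.0, 0.0]])
        np.testing.assert_array_equal(flip(img, "x"), img)

    def test_unknown_axis(self):
        with pytest.raises(AugmentationError):
            flip(np.zeros((2, 2)), "z")


class TestZoom:
    def test_unit_scale_identity(self, rng):
        img = rng.random((32, 32))
        np.testing.assert_array_equal(zoom(img, 1.0), img)

    def test_constant_image_invariant(self):
        img = np.full((40, 40), 0.6)
        for scale in (0.8, 0.9, 1.1, 1.2):
            np.testing.assert_allclose(zoom(img, scale), 0.6, atol=1e-9)

    def test_enlarges_centered_square_by_measured_factor(self):
        img = np.zeros((100, 100))
        img[30:70, 30:70] = 1.0
        out = zoom(img, 1.2)
        width = int((out[50] > 0.5).sum())
        assert abs(width - round(40 * 1.2)) <= 1

    def test_shrinks_with_reflective_padding(self):
        img = np.ones((50, 50)) * 0.8
        out = zoom(img, 0.8)
        assert out.shape == (50, 50)
        np.testing.assert_allclose(out, 0.8, atol=1e-9)

    def test_shape_always_preserved(self, rng):
        img = rng.random((33, 47))
        for scale in (0.8, 0.93, 1.07, 1.2):
            assert zoom(img, scale).shape == (33, 47)

    def test_out_of_range_scale_rejected(self, rng):
        with pytest.raises(AugmentationError):
            zoom(rng.random((10, 10)), 1.5)


class TestHistogramMatch:
    def test_self_reference_preserves_histogram(self, rng):
        img = rng.random((32, 32))
        out = histogram_match(img, img)
        np.testing.assert_array_equal(histogram_counts(out),
                                      histogram_counts(img))

    def test_constant_image_maps_to_single_level(self):
        img = np.full((16, 16), 0.2)
        ref = np.clip(np.linspace(0, 1, 256).reshape(16, 16), 0, 1)
        out = histogram_match(img, ref)
        assert np.unique(out).size == 1
        # all mass sits at the top of the reference CDF
        assert out.flat[0] > 0.9

    def test_two_level_image_matches_specification_oracle(self):
        img = np.array([[0.1, 0.1, 0.7, 0.7],
                        [0.1, 0.7, 0.7, 0.7],
                        [0.1, 0.1, 0.1, 0.7],
                        [0.7, 0.1, 0.7, 0.1]])
        ref = np.linspace(0.0, 0.999, 64).repeat(4).reshape(16, 16)
        out = histogram_match(img, ref)
        expected = specification_oracle(img, ref)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_monotone_mapping(self, rng):
        img = rng.random((24, 24))
        ref = rng.random((24, 24)) ** 2
        out = histogram_match(img, ref)
        order = np.argsort(img.ravel())
        assert np.all(np.diff(out.ravel()[order]) >= -1e-12)

    def test_emd_to_reference_never_increases(self):
        """Matching moves every generated image's histogram toward the
        reference in 64-bin earth-mover distance."""
        ref = generate_mmode(MmodeSpec(seed=99), SWINE_DOMAIN).pixels
        for i in range(10):
            img = generate_mmode(MmodeSpec(seed=200 + i, ptx_positive=i % 2 == 0),
                                 PHANTOM_DOMAIN).pixels
            out = histogram_match(img, ref)
            assert emd_64bin(out, ref) <= emd_64bin(img, ref) + 1e-9

    def test_rejects_multichannel_and_out_of_range(self, rng):
        with pytest.raises(AugmentationError):
            histogram_match(rng.random((4, 4, 3)), rng.random((4, 4)))
        with pytest.raises(AugmentationError):
            histogram_match(rng.random((4, 4)) + 2.0, rng.random((4, 4)))


class TestJitter:
    def test_zero_brightness_identity(self, rng):
        img = rng.random((16, 16))
        np.testing.assert_array_equal(jitter(img, "brightness", amount=0.0), img)

    def test_unit_contrast_identity(self, rng):
        img = rng.random((16, 16))
        np.testing.assert_allclose(jitter(img, "contrast", amount=1.0), img)

    def test_midgray_is_contrast_fixed_point(self):
        img = np.full((8, 8), 0.5)
        for g in (0.7, 1.0, 1.4):
            np.testing.assert_allclose(jitter(img, "contrast", amount=g), 0.5)

    def test_seeded_determinism_and_range(self, rng):
        img = rng.random((16, 16))
        a = jitter(img, "brightness", seed=5)
        b = jitter(img, "brightness", seed=5)
        np.testing.assert_array_equal(a, b)
        assert a.min() >= 0.0 and a.max() <= 1.0

    def test_unknown_kind(self, rng):
        with pytest.raises(AugmentationError):
            jitter(rng.random((4, 4)), "hue")


class TestBuildTrainingSet:
    @pytest.fixture()
    def roles(self, rng):
        return {
            "train": (rng.random((10, 16, 16)), np.arange(10) % 2),
            "validation": (rng.random((4, 16, 16)), np.arange(4) % 2),
            "test": (rng.random((4, 16, 16)), np.arange(4) % 2),
        }

    def test_level0_is_bit_identical(self, roles):
        out, manifest = build_training_set(roles, AugmentationPlan(level=0))
        for role in roles:
            np.testing.assert_array_equal(out[role][0], roles[role][0])
        assert manifest == []

    def test_level1_touches_only_training_and_keeps_count(self, roles, rng):
        plan = AugmentationPlan(level=1, seed=3)
        out, manifest = build_training_set(roles, plan)
        assert out["train"][0].shape[0] == 10
        np.testing.assert_array_equal(out["validation"][0],
                                      roles["validation"][0])
        np.testing.assert_array_equal(out["test"][0], roles["test"][0])
        assert all(m["operator"] == "flip_zoom" for m in manifest)

    def test_level2_matches_every_role(self, roles, rng):
        ref = rng.random((16, 16))
        plan = AugmentationPlan(level=2, reference=ref, seed=3)
        out, _ = build_training_set(roles, plan)
        for role in ("train", "validation", "test"):
            for img in out[role][0]:
                assert emd_64bin(img, ref) <= 1.0

    def test_level3_doubles_training_count_only(self, roles, rng):
        ref = rng.random((16, 16))
        plan = AugmentationPlan(level=3, reference=ref, seed=3)
        out, _ = build_training_set(roles, plan)
        assert out["train"][0].shape[0] == 20
        assert out["validation"][0].shape[0] == 4
        # labels duplicated pairwise with their source image
        np.testing.assert_array_equal(out["train"][1][::2], roles["train"][1])
        np.testing.assert_array_equal(out["train"][1][1::2], roles["train"][1])

    def test_deterministic_under_fixed_seed(self, roles, rng):
        ref = rng.random((16, 16))
        plan = AugmentationPlan(level=3, reference=ref, seed=11)
        a, _ = build_training_set(roles, plan)
        b, _ = build_training_set(roles, plan)
        np.testing.assert_array_equal(a["train"][0], b["train"][0])

    def test_missing_reference_is_configuration_error(self):
        with pytest.raises(AugmentationError):
            AugmentationPlan(level=2)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(level=st.integers(0, 3), seed=st.integers(0, 999))
    def test_all_levels_preserve_shape_and_range(self, level, seed):
        rng = np.random.default_rng(7)
        roles = {"train": (rng.random((4, 12, 12)), np.arange(4) % 2)}
        ref = rng.random((12, 12))
        plan = AugmentationPlan(level=level, reference=ref, seed=seed)
        out, _ = build_training_set(roles, plan)
        X = out["train"][0]
        assert X.shape[1:] == (12, 12)
        assert X.min() >= 0.0 and X.max() <= 1.0
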