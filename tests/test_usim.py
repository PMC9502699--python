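"""Generator tests: sonographic structure, determinism, domain behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ptxmode.usim import (BmodeClip, DomainParams, MmodeSpec, ParameterError,
                          PHANTOM_DOMAIN, SWINE_DOMAIN, generate_bmode_clip,
                          generate_mmode, load_dataset, make_dataset,
                          save_dataset)
from tests.conftest import lag1_column_diff, sub_pleural


class TestMmode:
    def test_width_follows_duration_and_rate(self):
        im = generate_mmode(MmodeSpec(duration_s=5, px_per_s=100, seed=1),
                            PHANTOM_DOMAIN)
        assert im.pixels.shape == (128, 500)

    def test_seashore_vs_barcode_texture_margin(self, phantom_pair):
        """Sub-pleural lag-1 column variation: granular speckle must exceed
        laminar barcode by at least a factor of 3 at the same seed."""
        neg, pos = phantom_pair
        assert lag1_column_diff(neg) >= 3.0 * lag1_column_diff(pos)

    def test_noiseless_barcode_rows_are_constant(self):
        dom = DomainParams(noise_sd=0.0)
        pos = generate_mmode(MmodeSpec(ptx_positive=True, seed=3), dom)
        sub = sub_pleural(pos)
        # every row is exactly constant across time (zero column variance)
        assert np.all(sub == sub[:, :1])

    def test_pleural_line_is_top_decile_bright(self, phantom_pair):
        neg, _ = phantom_pair
        band = neg.pixels[neg.pleural_row:neg.pleural_row + 2, :]
        assert band.mean() >= np.percentile(neg.pixels, 90)

    def test_chest_wall_is_laminar(self, phantom_pair):
        """Column-to-column variation above the pleura stays far below the
        speckle variation beneath it."""
        neg, _ = phantom_pair
        chest = neg.pixels[:neg.pleural_row, :]
        chest_diff = np.abs(np.diff(chest, axis=1)).mean()
        assert chest_diff < 0.5 * lag1_column_diff(neg)

    def test_deterministic_for_fixed_seed(self):
        spec = MmodeSpec(ptx_positive=False, seed=7)
        a = generate_mmode(spec, SWINE_DOMAIN)
        b = generate_mmode(spec, SWINE_DOMAIN)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(duration=st.floats(0.5, 8.0), rate=st.floats(10.0, 150.0),
           positive=st.booleans(), seed=st.integers(0, 10_000))
    def test_geometry_and_range_invariants(self, duration, rate, positive, seed):
        spec = MmodeSpec(duration_s=duration, px_per_s=rate,
                         ptx_positive=positive, seed=seed)
        im = generate_mmode(spec, PHANTOM_DOMAIN)
        assert im.pixels.shape[1] == round(duration * rate)
        assert im.pixels.min() >= 0.0 and im.pixels.max() <= 1.0

    def test_texture_feature_separates_classes(self):
        """A single threshold on the sub-pleural lag-1 feature classifies
        barcode vs seashore with >= 99% accuracy at noise_sd <= 0.05."""
        dom = DomainParams(noise_sd=0.05)
        feats, labels = [], []
        for i in range(100):
            for positive in (False, True):
                spec = MmodeSpec(ptx_positive=positive, seed=40_000 + 2 * i + positive)
                feats.append(lag1_column_diff(generate_mmode(spec, dom)))
                labels.append(positive)
        feats, labels = np.asarray(feats), np.asarray(labels)
        best = max(np.mean((feats < thr) == labels)
                   for thr in np.linspace(feats.min(), feats.max(), 256))
        assert best >= 0.99

    def test_domain_shift_preserves_labels(self):
        """Same seed rendered in both domains: identical class labels,
        different intensity maps."""
        for seed in range(5):
            spec = MmodeSpec(ptx_positive=seed % 2 == 1, seed=seed)
            ph = generate_mmode(spec, PHANTOM_DOMAIN)
            sw = generate_mmode(spec, SWINE_DOMAIN)
            assert ph.label == sw.label
            assert not np.array_equal(ph.pixels, sw.pixels)

    def test_positive_class_confound_brightens(self):
        """The phantom domain's class-correlated brightness bias makes
        positive renders globally brighter than negatives."""
        means = {p: np.mean([
            generate_mmode(MmodeSpec(ptx_positive=p, seed=60_000 + i),
                           PHANTOM_DOMAIN).pixels.mean()
            for i in range(5)]) for p in (False, True)}
        assert means[True] > means[False] + 0.05

    @pytest.mark.parametrize("bad", [
        dict(brightness_offset=0.7),
        dict(contrast_gain=0.0),
        dict(pleural_depth_frac=1.0),
        dict(speckle_grain_px=0.5),
        dict(noise_sd=-0.1),
    ])
    def test_invalid_domain_raises_naming_field(self, bad):
        with pytest.raises(ParameterError) as err:
            DomainParams(**bad)
        assert next(iter(bad)) in str(err.value)

    @pytest.mark.parametrize("bad", [
        dict(duration_s=0), dict(px_per_s=0.5), dict(respiration_rpm=-1),
    ])
    def test_invalid_spec_raises_naming_field(self, bad):
        with pytest.raises(ParameterError) as err:
            MmodeSpec(**bad)
        assert next(iter(bad)) in str(err.value)


class TestBmode:
    def test_six_seconds_at_ten_fps_yields_sixty_frames(self):
        clip = generate_bmode_clip(6, 10, False, PHANTOM_DOMAIN, seed=1)
        assert len(clip.frames) == 60

    def test_frame_shapes_consistent(self):
        clip = generate_bmode_clip(2, 5, True, PHANTOM_DOMAIN, seed=1)
        shapes = {f.shape for f in clip.frames}
        assert len(shapes) == 1

    def test_positive_clip_has_no_sliding(self):
        """With no sensor noise, a PTX-positive stack is a frozen anatomy:
        every frame below the pleura is identical (zero lateral lag)."""
        dom = DomainParams(noise_sd=0.0)
        clip = generate_bmode_clip(2, 10, True, dom, seed=2)
        first = clip.frames[0]
        for frame in clip.frames[1:]:
            np.testing.assert_array_equal(frame, first)

    def test_negative_clip_slides(self):
        dom = DomainParams(noise_sd=0.0)
        clip = generate_bmode_clip(2, 10, False, dom, seed=2)
        assert any(not np.array_equal(clip.frames[0], f)
                   for f in clip.frames[1:])

    def test_rib_shadows_are_dark(self):
        dom = DomainParams(noise_sd=0.0)
        clip = generate_bmode_clip(1, 5, False, dom, seed=3)
        frame = clip.frames[0]
        h = frame.shape[0]
        shadow_cols = frame[h // 2:, list(clip.rib_positions)]
        mid = (clip.rib_positions[0] + clip.rib_positions[1]) // 2
        open_cols = frame[h // 2:, [mid]]
        assert shadow_cols.mean() < 0.5 * open_cols.mean()

    def test_determinism_and_frame_count_rounding(self):
        a = generate_bmode_clip(6, 7, False, PHANTOM_DOMAIN, seed=4)
        b = generate_bmode_clip(6, 7, False, PHANTOM_DOMAIN, seed=4)
        assert len(a.frames) == 42
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa, fb)

    def test_invalid_duration_or_fps(self):
        with pytest.raises(ParameterError):
            generate_bmode_clip(0, 10, False, PHANTOM_DOMAIN)
        with pytest.raises(ParameterError):
            generate_bmode_clip(6, 0.2, False, PHANTOM_DOMAIN)


class TestDataset:
    def test_balanced_counts(self):
        images = make_dataset(3, MmodeSpec(duration_s=1.0), PHANTOM_DOMAIN,
                              seed=9)
        assert len(images) == 6
        assert sum(im.spec.ptx_positive for im in images) == 3

    def test_single_pair(self):
        images = make_dataset(1, MmodeSpec(duration_s=1.0), PHANTOM_DOMAIN)
        assert len(images) == 2

    def test_seed_derivation_extends_without_reshuffle(self):
        small = make_dataset(2, MmodeSpec(duration_s=1.0), PHANTOM_DOMAIN, seed=5)
        large = make_dataset(4, MmodeSpec(duration_s=1.0), PHANTOM_DOMAIN, seed=5)
        for a, b in zip(small, large):
            np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_disk_roundtrip_is_deterministic(self, tmp_path):
        spec = MmodeSpec(duration_s=1.0)
        for sub in ("a", "b"):
            make_dataset(2, spec, SWINE_DOMAIN, seed=11,
                         out_dir=tmp_path / sub)
        for pa, pb in zip(sorted((tmp_path / "a").rglob("*.png")),
                          sorted((tmp_path / "b").rglob("*.png"))):
            assert pa.read_bytes() == pb.read_bytes()
        images, labels = load_dataset(tmp_path / "a")
        assert sorted(labels) == ["negative", "negative", "positive", "positive"]
        assert all(im.min() >= 0 and im.max() <= 1 for im in images)

    def test_rejects_empty_request(self):
        with pytest.raises(ParameterError):
            make_dataset(0, MmodeSpec(), PHANTOM_DOMAIN)
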