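"""Synthetic generator: geometry, pulse injection, print transform, manifests."""

import numpy as np
import pandas as pd
import pytest

from veinlive.synth import (NoiseModel, PulseModel, SceneConfig,
                            finger_region_mask, finger_transmission,
                            generate_dataset, generate_vein_pattern,
                            iter_dataset, prepare_print_pattern,
                            render_clip, species_allocation)


class TestVeinPattern:
    def test_empty_when_no_veins(self):
        cfg = SceneConfig(width=80, height=60, n_main_veins=0, seed=1)
        A, mask = generate_vein_pattern(cfg)
        assert not mask.any()
        assert A.max() == 0

    def test_deterministic_in_seed(self):
        cfg = SceneConfig(width=120, height=90, seed=42)
        A1, m1 = generate_vein_pattern(cfg)
        A2, m2 = generate_vein_pattern(cfg)
        assert np.array_equal(A1, A2) and np.array_equal(m1, m2)

    def test_zero_outside_finger(self):
        cfg = SceneConfig(width=120, height=90, seed=3)
        A, _ = generate_vein_pattern(cfg)
        finger = finger_region_mask(cfg)
        assert np.all(A[~finger] == 0)

    def test_mask_is_threshold_of_map(self):
        cfg = SceneConfig(width=120, height=90, seed=5)
        A, mask = generate_vein_pattern(cfg)
        assert np.array_equal(mask, A > 0.1 * A.max())

    def test_default_coverage_over_seeds(self):
        """Veins cover a plausible 2-15% of the finger at default geometry."""
        covs = []
        for seed in range(50):
            cfg = SceneConfig(seed=seed)
            _, mask = generate_vein_pattern(cfg)
            covs.append(mask.sum() / finger_region_mask(cfg).sum())
        assert min(covs) >= 0.02 and max(covs) <= 0.15

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(width=0)


class TestRenderClip:
    def test_static_limit(self, small_pattern):
        """m = 0 and all noise off: every frame is identical."""
        A, mask, B = small_pattern
        clip, _ = render_clip(A, mask, PulseModel(depth=0.0, f_heart=1.2),
                              NoiseModel(gaussian_sigma=0.0), live=True,
                              base_transmission=B, seed=1, n_frames=16)
        assert all(np.array_equal(clip.frames[0], f) for f in clip.frames)

    def test_shape_contract(self, small_pattern):
        A, mask, B = small_pattern
        clip, _ = render_clip(A, mask, PulseModel(f_heart=1.2), NoiseModel(),
                              live=True, base_transmission=B, seed=1,
                              fps=120.0, n_frames=180)
        assert clip.shape == (180, 120, 160, 3)

    def test_spectral_peak_at_heart_rate(self, clean_live_clip):
        """Noise-free mean trace peaks (non-DC) at the bin nearest f_heart."""
        _, gt = clean_live_clip
        freqs = np.fft.rfftfreq(gt.mean_trace.shape[0], 1.0 / 120.0)
        for c in range(3):
            tr = gt.mean_trace[:, c]
            spec = np.abs(np.fft.rfft(tr - tr.mean()))
            peak = freqs[spec[1:].argmax() + 1]
            nearest = freqs[np.abs(freqs - gt.f_heart).argmin()]
            assert peak == pytest.approx(nearest)

    def test_live_attack_identical_when_depth_zero(self, small_pattern):
        A, mask, B = small_pattern
        kw = dict(base_transmission=B, seed=5, n_frames=24)
        p0 = PulseModel(depth=0.0, f_heart=1.1)
        live, _ = render_clip(A, mask, p0, NoiseModel(), live=True, **kw)
        attack, _ = render_clip(A, mask, p0, NoiseModel(), live=False, **kw)
        assert np.array_equal(live.frames, attack.frames)

    def test_variance_monotone_in_depth(self, small_pattern):
        """Pre-normalisation vein-mean temporal variance grows with m."""
        A, mask, B = small_pattern
        variances = []
        for m in (0.0, 0.01, 0.02, 0.04):
            _, gt = render_clip(A, mask, PulseModel(depth=m, f_heart=1.3),
                                NoiseModel(gaussian_sigma=0.0), live=True,
                                base_transmission=B, seed=2, quantize=False)
            variances.append(gt.mean_trace[:, 0].var())
        assert all(b > a for a, b in zip(variances, variances[1:]))

    def test_shape_mismatch_rejected(self, small_pattern):
        A, mask, B = small_pattern
        with pytest.raises(ValueError):
            render_clip(A[:-1], mask, PulseModel(), NoiseModel(), live=True)


@pytest.fixture(scope="module")
def vein_image():
    """Low-contrast noisy vein image over flat tissue (no silhouette)."""
    cfg = SceneConfig(width=160, height=120, seed=9, n_main_veins=4)
    A, _ = generate_vein_pattern(cfg)
    rng = np.random.default_rng(0)
    img = 150.0 * np.exp(-0.12 * A) + rng.normal(0, 1.5, A.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


class TestPrintPattern:

    def test_identity_exponent_matches_equalized(self, vein_image):
        out = prepare_print_pattern(vein_image, blur_sigma=0.0, gamma=1.0)
        ref = prepare_print_pattern(vein_image, blur_sigma=0.0,
                                    gamma=1.0 + 1e-12)
        assert np.array_equal(out, ref)

    def test_contrast_increases(self, vein_image):
        from veinlive.synth import finger_region_mask
        region = finger_region_mask(SceneConfig(width=160, height=120, seed=9,
                                                n_main_veins=4))
        out = prepare_print_pattern(vein_image.astype(np.float64),
                                    blur_sigma=1.0, clahe_clip=0.02, gamma=1.0)
        assert out[region].std() > vein_image[region].std()

    def test_shape_dtype_preserved(self, vein_image):
        out = prepare_print_pattern(vein_image)
        assert out.shape == vein_image.shape and out.dtype == vein_image.dtype

    @pytest.mark.parametrize("gamma", [0.0, -1.5])
    def test_invalid_gamma(self, vein_image, gamma):
        with pytest.raises(ValueError):
            prepare_print_pattern(vein_image, gamma=gamma)

    def test_multichannel_rejected(self):
        with pytest.raises(ValueError):
            prepare_print_pattern(np.zeros((8, 8, 3)))


class TestDataset:
    CFG = SceneConfig(width=64, height=48, duration=0.1)

    def test_bookkeeping(self):
        manifest = generate_dataset(4, 2, config=self.CFG, seed=3)
        assert len(manifest) == 6
        live = manifest[manifest.label == "bona_fide"]
        assert live.finger_id.nunique() == 2
        assert (live.finger_id.value_counts() == 2).all()

    def test_deterministic(self):
        m1 = generate_dataset(4, 2, config=self.CFG, seed=3)
        m2 = generate_dataset(4, 2, config=self.CFG, seed=3)
        pd.testing.assert_frame_equal(m1, m2)

    def test_proportional_species_allocation(self):
        assert species_allocation(10) == {"a4_paper": 4, "pvc": 3,
                                          "laser_film": 3}
        manifest = generate_dataset(20, 10, config=self.CFG, seed=1)
        counts = manifest[manifest.label == "attack"].species.value_counts()
        assert counts["a4_paper"] == 4 and counts["pvc"] == 3 \
            and counts["laser_film"] == 3

    def test_bad_species_mix_rejected(self):
        with pytest.raises(ValueError):
            list(iter_dataset(2, 3, species_mix={"pvc": 1}, config=self.CFG))

    def test_writes_clips_and_manifest(self, tmp_path):
        generate_dataset(2, 1, config=self.CFG, seed=0, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        manifest = pd.read_csv(tmp_path / "manifest.csv")
        assert len(manifest) == 3
        for p in manifest.path:
            assert (tmp_path / p).exists()
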