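"""Block-mean signals, multi-scale aggregation, normalisation, MSTmap."""

import numpy as np
import pytest

from veinlive.blocks import BlockSet
from veinlive.mstmap import (BlockSignalMatrix, block_mean_signals,
                             clip_to_mstmap, multiscale_aggregate,
                             normalize_rows, to_mstmap)
from veinlive.video import VideoClip


def _blocks(centers, size=8):
    return BlockSet(centers=centers, block_size=size)


class TestBlockMeanSignals:
    def test_constant_clip(self):
        clip = VideoClip(np.full((6, 32, 48, 3), 55.0))
        sig = block_mean_signals(clip, _blocks([(10, 10), (10, 30)]))
        assert np.allclose(sig.values, 55.0)
        assert sig.values.shape == (2, 6, 3)

    def test_injected_sinusoid_correlation(self):
        """A sinusoid added uniformly inside a block is recovered with
        correlation >= 0.99 at zero noise."""
        T = 64
        s = np.sin(2 * np.pi * 1.5 * np.arange(T) / 30.0)
        frames = np.full((T, 24, 24, 3), 100.0, np.float32)
        frames[:, 8:16, 8:16, :] += 3.0 * s[:, None, None, None]
        sig = block_mean_signals(VideoClip(frames), _blocks([(12, 12)]))
        for c in range(3):
            r = np.corrcoef(sig.values[0, :, c], s)[0, 1]
            assert r >= 0.99


class TestMultiscale:
    def test_unit_scale_identity(self):
        rng = np.random.default_rng(0)
        m = BlockSignalMatrix(rng.random((5, 7, 3)))
        out = multiscale_aggregate(m, scales=(1,))
        assert np.array_equal(out.values, m.values)

    def test_hand_computed_pairs(self):
        vals = np.arange(4 * 2 * 3, dtype=float).reshape(4, 2, 3)
        out = multiscale_aggregate(BlockSignalMatrix(vals), scales=(2,))
        assert out.values.shape == (2, 2, 3)
        assert np.allclose(out.values[0], (vals[0] + vals[1]) / 2)
        assert np.allclose(out.values[1], (vals[2] + vals[3]) / 2)

    def test_default_row_count_for_p56(self):
        m = BlockSignalMatrix(np.zeros((56, 10, 3)))
        out = multiscale_aggregate(m)  # scales (1, 2, 4, 8)
        assert out.values.shape[0] == 56 + 28 + 14 + 7  # = 105

    def test_scale_exceeding_p_rejected(self):
        with pytest.raises(ValueError):
            multiscale_aggregate(BlockSignalMatrix(np.zeros((4, 5, 3))),
                                 scales=(8,))


class TestNormalizeRows:
    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = BlockSignalMatrix(rng.random((6, 20, 3)))
        y = BlockSignalMatrix(2.5 * x.values + 17.0)
        assert np.allclose(normalize_rows(x).values, normalize_rows(y).values)

    def test_constant_row_neutral(self):
        out = normalize_rows(BlockSignalMatrix(np.full((2, 9, 3), 42.0)))
        assert np.all(out.values == 128.0)

    def test_range_attained(self):
        rng = np.random.default_rng(2)
        out = normalize_rows(BlockSignalMatrix(rng.random((8, 30, 3))))
        assert np.allclose(out.values.min(axis=1), 0.0)
        assert np.allclose(out.values.max(axis=1), 255.0)


class TestToMSTmap:
    def test_shape_contract(self):
        m = BlockSignalMatrix(np.random.default_rng(0).random((105, 180, 3))
                              * 255)
        out = to_mstmap(m)
        assert out.map.shape == (224, 180, 3)
        assert out.map.dtype == np.uint8

    def test_identity_resample_up_to_quantization(self):
        vals = np.random.default_rng(1).random((224, 180, 3)) * 255
        out = to_mstmap(BlockSignalMatrix(vals))
        assert np.abs(out.map.astype(float) - vals).max() <= 0.5 + 1e-9

    def test_row_upsample_monotone(self):
        """Interpolating between a 0-row and a 255-row is monotone."""
        vals = np.stack([np.zeros((12, 3)), np.full((12, 3), 255.0)])
        out = to_mstmap(BlockSignalMatrix(vals), out_rows=32, out_cols=12)
        col = out.map[:, 0, 0].astype(int)
        assert np.all(np.diff(col) >= 0)
        assert col[0] == 0 and col[-1] == 255

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            to_mstmap(BlockSignalMatrix(np.zeros((0, 5, 3))))


@pytest.fixture(scope="module")
def setup(clean_live_clip):
    clip, gt = clean_live_clip
    from veinlive.blocks import edge_map, select_blocks
    edges = edge_map(gt.vein_mask)
    blocks = select_blocks(edges, gt.vein_mask, p=16, block_size=8)
    return clip, gt, blocks


class TestEndToEndInvariances:

    def test_offset_gain_invariance(self, setup):
        clip, gt, blocks = setup
        mst1, _ = clip_to_mstmap(clip, blocks)
        shifted = VideoClip(clip.frames * 1.5 + 9.0, fps=clip.fps)
        mst2, _ = clip_to_mstmap(shifted, blocks)
        # min-max normalisation forces equality up to 8-bit rounding ties
        diff = np.abs(mst1.map.astype(int) - mst2.map.astype(int))
        assert diff.max() <= 1
        assert (diff > 0).mean() < 0.01

    def test_pulse_recovery_in_scale1_rows(self, setup):
        """Dominant non-DC frequency of every scale-1 row is within one DFT
        bin of the injected heart rate."""
        clip, gt, blocks = setup
        _, multi = clip_to_mstmap(clip, blocks)
        T = multi.values.shape[1]
        freqs = np.fft.rfftfreq(T, 1.0 / clip.fps)
        for row in range(blocks.p):       # scale-1 rows come first
            tr = multi.values[row, :, 0]
            spec = np.abs(np.fft.rfft(tr - tr.mean()))
            peak = freqs[spec[1:].argmax() + 1]
            assert abs(peak - gt.f_heart) <= freqs[1] + 1e-9

    def test_live_rows_more_variable_than_static(self, setup):
        from veinlive.synth import (NoiseModel, PulseModel, render_clip,
                                    SceneConfig, generate_vein_pattern,
                                    finger_transmission)
        clip, gt, blocks = setup
        cfg = SceneConfig(width=160, height=120, seed=7)
        A, mask = generate_vein_pattern(cfg)
        B = finger_transmission(cfg)
        static, _ = render_clip(A, mask, PulseModel(depth=0.0, f_heart=1.4),
                                NoiseModel(gaussian_sigma=0.0), live=True,
                                base_transmission=B, seed=11, quantize=False)
        _, live_multi = clip_to_mstmap(clip, blocks)
        _, static_multi = clip_to_mstmap(static, blocks)
        lv = live_multi.values.var(axis=1)
        sv = static_multi.values.var(axis=1)
        assert np.all(lv > sv)
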