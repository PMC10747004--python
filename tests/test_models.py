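"""MN block, L-ViT block, Light-ViT backbone and baseline factories."""

import numpy as np
import pytest

from veinlive.models import (LViTBlock, LViTBlockSpec, LightViT, MNBlock,
                             MNBlockSpec, build_baseline, build_light_vit,
                             count_parameters, fold_patches, params_millions,
                             reduced_light_vit_config,
                             reference_light_vit_config, unfold_patches,
                             mstmap_to_input)
from veinlive.nn import Tensor, softmax


RNG = np.random.default_rng(0)


class TestMNBlock:
    def test_stride_two_halves_spatial_dims(self):
        block = MNBlock(MNBlockSpec(8, 16, stride=2), RNG)
        out = block(Tensor(np.zeros((1, 8, 32, 32), np.float32)))
        assert out.shape == (1, 16, 16, 16)

    def test_parameter_count_formula(self):
        """in=4, out=4, expansion=2: 32+16+72+16+32+8 = 176 parameters."""
        block = MNBlock(MNBlockSpec(4, 4, stride=1, expansion=2), RNG)
        assert count_parameters(block) == 176

    def test_residual_identity_with_zero_weights(self):
        block = MNBlock(MNBlockSpec(4, 4, stride=1), RNG)
        for p in block.parameters():
            p.data[...] = 0.0
        block.eval()
        x = np.random.default_rng(1).standard_normal((2, 4, 8, 8))
        out = block(Tensor(x))
        assert np.allclose(out.data, x, atol=1e-6)

    def test_channel_mismatch_rejected(self):
        block = MNBlock(MNBlockSpec(4, 8), RNG)
        with pytest.raises(ValueError):
            block(Tensor(np.zeros((1, 5, 8, 8), np.float32)))

    def test_invalid_stride(self):
        with pytest.raises(ValueError):
            MNBlockSpec(4, 4, stride=3)


class TestLViTBlock:
    def test_patch_arithmetic(self):
        """8x8 feature map with 2x2 patches: N = 16 patches of P = 4 pixels."""
        x = Tensor(np.random.default_rng(2).standard_normal((1, 4, 8, 8)))
        tokens = unfold_patches(x, (2, 2))
        assert tokens.shape == (1, 4, 16, 4)

    def test_shape_preserved(self):
        spec = LViTBlockSpec(8, 16, depth=1, patch=(2, 2))
        block = LViTBlock(spec, (8, 8), RNG)
        out = block(Tensor(np.zeros((2, 8, 8, 8), np.float32)))
        assert out.shape == (2, 8, 8, 8)

    def test_unfold_fold_inverse(self):
        x = Tensor(np.random.default_rng(3).standard_normal((2, 6, 8, 12)))
        back = fold_patches(unfold_patches(x, (2, 2)), (2, 2), (8, 12))
        assert np.array_equal(back.data, x.data)

    def test_indivisible_dims_rejected(self):
        spec = LViTBlockSpec(8, 16, depth=1, patch=(2, 2))
        with pytest.raises(ValueError):
            LViTBlock(spec, (7, 8), RNG)

    def test_token_dim_head_divisibility(self):
        with pytest.raises(ValueError):
            LViTBlockSpec(8, 10, depth=1, heads=4)


class TestLightViT:
    def test_forward_contract_and_softmax(self):
        model = build_light_vit(reduced_light_vit_config(48), seed=0)
        model.eval()
        x = np.random.default_rng(4).standard_normal((2, 3, 48, 48))
        out = model(Tensor(x.astype(np.float32)))
        assert out.shape == (2, 2)
        probs = softmax(out, axis=1).data
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_reference_parameter_bracket(self):
        """Reference backbone lands in [0.9 M, 1.3 M] parameters."""
        n = count_parameters(build_light_vit(reference_light_vit_config()))
        assert 0.9e6 <= n <= 1.3e6

    def test_seeded_initialisation_deterministic(self):
        cfg = reduced_light_vit_config(48)
        m1, m2 = build_light_vit(cfg, seed=9), build_light_vit(cfg, seed=9)
        x = Tensor(np.random.default_rng(5)
                   .standard_normal((1, 3, 48, 48)).astype(np.float32))
        m1.eval(), m2.eval()
        assert np.array_equal(m1(x).data, m2(x).data)

    def test_invalid_stage_chaining(self):
        from veinlive.models import LightViTConfig
        bad = LightViTConfig(stages=(MNBlockSpec(16, 24, 2),
                                     MNBlockSpec(16, 24, 1)),
                             stem_channels=16)
        with pytest.raises(ValueError):
            build_light_vit(bad)

    def test_mstmap_preprocessing(self):
        m = (np.random.default_rng(6).random((224, 180, 3)) * 255
             ).astype(np.uint8)
        x = mstmap_to_input(m, 48)
        assert x.shape == (3, 48, 48)
        assert x.min() >= -1.0 and x.max() <= 1.0


class TestBaselines:
    @pytest.mark.parametrize("name,expected", [
        ("mobilenet_v2", 2_226_434),
        ("resnet50", 23_512_130),
    ])
    def test_exact_counts(self, name, expected):
        model = build_baseline(name, num_classes=2)
        assert count_parameters(model) == expected

    def test_vgg16_count_and_millions(self):
        model = build_baseline("vgg16", num_classes=2)
        assert count_parameters(model) == 134_268_738
        assert params_millions(model) == 134.269

    def test_vit_b16_structure_count(self):
        """Standard 2-class ViT-B/16 (the published variant differs slightly)."""
        model = build_baseline("vit_b16", num_classes=2)
        assert count_parameters(model) == 85_800_194

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            build_baseline("alexnet")

    def test_head_resizing(self):
        m5 = build_baseline("mobilenet_v2", num_classes=5)
        m2 = build_baseline("mobilenet_v2", num_classes=2)
        assert count_parameters(m5) - count_parameters(m2) == 3 * 1281
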