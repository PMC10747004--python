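"""Liveness classification networks.

The classifier is a lightweight hybrid CNN-transformer ("Light-ViT"): a
strided stem convolution followed by alternating stages of

* **MN blocks** — inverted-residual depthwise-separable convolutions
  (pointwise expand -> norm -> SiLU -> 3x3 depthwise, stride T -> norm ->
  SiLU -> pointwise project -> norm; identity residual when the stride is 1
  and the channel count is preserved), and
* **L-ViT blocks** — local 3x3 convolution, 1x1 projection to token
  dimension D, unfolding the feature map into N patches of P pixels,
  learned positional encoding, L pre-norm self-attention encoder layers,
  folding back, 1x1 projection to C channels, channel concatenation with the
  block input and a 3x3 fusion convolution,

ending in a 1x1 convolution, global average pooling and a linear 2-class
head.  Baseline factories build the standard published VGG-16, ResNet-50,
MobileNetV2 and ViT-B/16 architectures with resized classification heads for
parameter-count comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn import (Module, Sequential, Conv2d, BatchNorm2d, LayerNorm, Linear,
                 SiLU, ReLU, GELU, MaxPool2d, Flatten, EncoderLayer,
                 Parameter, Tensor, concat, global_avg_pool, softmax,
                 count_parameters)

__all__ = [
    "MNBlockSpec", "LViTBlockSpec", "LightViTConfig",
    "MNBlock", "LViTBlock", "LightViT",
    "build_light_vit", "reference_light_vit_config",
    "reduced_light_vit_config", "build_baseline", "BASELINES",
    "count_parameters", "params_millions", "mstmap_to_input",
]


# ---------------------------------------------------------------------------
# Stage specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MNBlockSpec:
    """Inverted-residual block: expand -> depthwise (stride) -> project."""

    in_ch: int
    out_ch: int
    stride: int = 1
    expansion: float = 2.0

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")

    @property
    def residual(self) -> bool:
        return self.stride == 1 and self.in_ch == self.out_ch


@dataclass(frozen=True)
class LViTBlockSpec:
    """Hybrid conv/attention block operating on C-channel feature maps with
    D-dimensional tokens, patch (w, h) and L encoder layers."""

    channels: int
    token_dim: int
    depth: int
    patch: tuple[int, int] = (2, 2)
    heads: int = 4
    mlp_ratio: float = 2.0

    def __post_init__(self):
        if self.token_dim % self.heads:
            raise ValueError("token_dim must be divisible by heads")


@dataclass(frozen=True)
class LightViTConfig:
    """Backbone: stem -> ordered MN / L-ViT stages -> 1x1 conv -> pool -> fc."""

    stages: tuple
    in_size: tuple[int, int] = (224, 224)
    in_channels: int = 3
    stem_channels: int = 16
    head_channels: int = 320
    num_classes: int = 2


def reference_light_vit_config() -> LightViTConfig:
    """Default backbone (~1.0 M parameters at 224 x 224 input).

    The last attention stage runs on a 7 x 7 feature map, so it uses a 1 x 1
    patch (plain token attention over all 49 positions).
    """
    return LightViTConfig(stages=(
        MNBlockSpec(16, 16, 1),
        MNBlockSpec(16, 24, 2),
        MNBlockSpec(24, 24, 1),
        MNBlockSpec(24, 24, 1),
        MNBlockSpec(24, 48, 2),
        LViTBlockSpec(48, 64, 2, patch=(2, 2)),
        MNBlockSpec(48, 64, 2),
        LViTBlockSpec(64, 80, 4, patch=(2, 2)),
        MNBlockSpec(64, 80, 2),
        LViTBlockSpec(80, 96, 3, patch=(1, 1)),
    ))


def reduced_light_vit_config(in_size: int = 48) -> LightViTConfig:
    """Small configuration (~70 k parameters) for desk-scale training."""
    return LightViTConfig(stages=(
        MNBlockSpec(8, 16, 2),
        LViTBlockSpec(16, 32, 1, patch=(2, 2)),
        MNBlockSpec(16, 24, 2),
        LViTBlockSpec(24, 40, 1, patch=(2, 2)),
    ), in_size=(in_size, in_size), stem_channels=8, head_channels=64)


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

def _conv_bn_silu(in_ch, out_ch, k, stride, rng, groups=1):
    return Sequential(
        Conv2d(in_ch, out_ch, k, stride=stride, padding=k // 2, groups=groups,
               bias=False, rng=rng),
        BatchNorm2d(out_ch), SiLU())


class MNBlock(Module):
    def __init__(self, spec: MNBlockSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        hidden = int(round(spec.in_ch * spec.expansion))
        self.expand = Conv2d(spec.in_ch, hidden, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(hidden)
        self.dw = Conv2d(hidden, hidden, 3, stride=spec.stride, padding=1,
                         groups=hidden, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(hidden)
        self.project = Conv2d(hidden, spec.out_ch, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(spec.out_ch)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.in_ch:
            raise ValueError(f"expected {self.spec.in_ch} channels, "
                             f"got {x.shape[1]}")
        y = self.bn1(self.expand(x)).silu()
        y = self.bn2(self.dw(y)).silu()
        y = self.bn3(self.project(y))
        return x + y if self.spec.residual else y


def unfold_patches(x: Tensor, patch: tuple[int, int]) -> Tensor:
    """(B, D, H, W) -> (B, P, N, D) with P = ph*pw pixels per patch and
    N = (H/ph)*(W/pw) patches."""
    B, D, H, W = x.shape
    ph, pw = patch
    if H % ph or W % pw:
        raise ValueError(f"feature dims {(H, W)} not divisible by patch {patch}")
    x = x.reshape(B, D, H // ph, ph, W // pw, pw)
    x = x.transpose(0, 3, 5, 2, 4, 1)              # (B, ph, pw, Hp, Wp, D)
    return x.reshape(B, ph * pw, (H // ph) * (W // pw), D)


def fold_patches(x: Tensor, patch: tuple[int, int], hw: tuple[int, int]) -> Tensor:
    """Inverse of :func:`unfold_patches`."""
    B, P, N, D = x.shape
    ph, pw = patch
    H, W = hw
    x = x.reshape(B, ph, pw, H // ph, W // pw, D)
    x = x.transpose(0, 5, 3, 1, 4, 2)              # (B, D, Hp, ph, Wp, pw)
    return x.reshape(B, D, H, W)


class LViTBlock(Module):
    def __init__(self, spec: LViTBlockSpec, feature_hw: tuple[int, int],
                 rng: np.random.Generator):
        super().__init__()
        C, D = spec.channels, spec.token_dim
        H, W = feature_hw
        ph, pw = spec.patch
        if H % ph or W % pw:
            raise ValueError(f"feature dims {feature_hw} not divisible by "
                             f"patch {spec.patch}")
        self.spec = spec
        self.feature_hw = (H, W)
        self.local = _conv_bn_silu(C, C, 3, 1, rng)
        self.to_tokens = Conv2d(C, D, 1, bias=False, rng=rng)
        P, N = ph * pw, (H // ph) * (W // pw)
        self.pos = Parameter(0.02 * rng.standard_normal((P, N, D)))
        self.encoder = Sequential(*[
            EncoderLayer(D, spec.heads, spec.mlp_ratio, rng=rng)
            for _ in range(spec.depth)])
        self.from_tokens = Conv2d(D, C, 1, bias=False, rng=rng)
        self.bn_out = BatchNorm2d(C)
        self.fusion = _conv_bn_silu(2 * C, C, 3, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if (H, W) != self.feature_hw:
            raise ValueError(f"expected {self.feature_hw} feature map, "
                             f"got {(H, W)}")
        y = self.local(x)
        y = self.to_tokens(y)
        tokens = unfold_patches(y, self.spec.patch) + self.pos
        Bp = tokens.shape
        seq = tokens.reshape(Bp[0] * Bp[1], Bp[2], Bp[3])
        seq = self.encoder(seq)
        tokens = seq.reshape(*Bp)
        y = fold_patches(tokens, self.spec.patch, (H, W))
        y = self.bn_out(self.from_tokens(y))
        fused = concat([x, y], axis=1)
        return self.fusion(fused)


# ---------------------------------------------------------------------------
# Backbone
# ---------------------------------------------------------------------------

class LightViT(Module):
    def __init__(self, config: LightViTConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        H, W = config.in_size
        self.stem = _conv_bn_silu(config.in_channels, config.stem_channels,
                                  3, 2, rng)
        H, W = (H - 1) // 2 + 1, (W - 1) // 2 + 1
        ch = config.stem_channels
        stages: list[Module] = []
        for spec in config.stages:
            if isinstance(spec, MNBlockSpec):
                if spec.in_ch != ch:
                    raise ValueError(f"stage chaining: expected in_ch={ch}, "
                                     f"spec has {spec.in_ch}")
                stages.append(MNBlock(spec, rng))
                if spec.stride == 2:
                    H, W = (H - 1) // 2 + 1, (W - 1) // 2 + 1
                ch = spec.out_ch
            elif isinstance(spec, LViTBlockSpec):
                if spec.channels != ch:
                    raise ValueError(f"stage chaining: expected channels={ch}, "
                                     f"spec has {spec.channels}")
                stages.append(LViTBlock(spec, (H, W), rng))
            else:
                raise TypeError(f"unknown stage spec {spec!r}")
        self.stages = stages
        self.head_conv = _conv_bn_silu(ch, config.head_channels, 1, 1, rng)
        self.fc = Linear(config.head_channels, config.num_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        for stage in self.stages:
            x = stage(x)
        x = self.head_conv(x)
        x = global_avg_pool(x)
        return self.fc(x)


def build_light_vit(config: LightViTConfig | None = None,
                    seed: int = 0) -> LightViT:
    """Construct a Light-ViT; stage chaining is validated at build time."""
    return LightViT(config or reference_light_vit_config(), seed=seed)


def mstmap_to_input(map_u8: np.ndarray, size: int | tuple[int, int] = 224
                    ) -> np.ndarray:
    """MSTmap (rows, cols, 3) uint8 -> model input (3, size, size) float32 in
    [-1, 1] (bilinear resize to a square grid)."""
    from skimage.transform import resize as sk_resize
    if isinstance(size, int):
        size = (size, size)
    x = map_u8.astype(np.float32) / 255.0
    if x.shape[:2] != size:
        x = sk_resize(x, (*size, 3), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
    return ((x - 0.5) / 0.5).transpose(2, 0, 1).astype(np.float32)


# ---------------------------------------------------------------------------
# Baseline architectures (standard published networks, 2-class heads)
# ---------------------------------------------------------------------------

def _vgg16(num_classes: int, rng) -> Module:
    cfg = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
           512, 512, 512, "M", 512, 512, 512, "M"]
    layers: list[Module] = []
    in_ch = 3
    for v in cfg:
        if v == "M":
            layers.append(MaxPool2d(2))
        else:
            layers.append(Conv2d(in_ch, v, 3, padding=1, bias=True, rng=rng))
            layers.append(ReLU())
            in_ch = v
    layers += [Flatten(),
               Linear(512 * 7 * 7, 4096, rng=rng), ReLU(),
               Linear(4096, 4096, rng=rng), ReLU(),
               Linear(4096, num_classes, rng=rng)]
    return Sequential(*layers)


class _Bottleneck(Module):
    expansion = 4

    def __init__(self, inplanes, planes, stride, rng):
        super().__init__()
        out = planes * self.expansion
        self.conv1 = Conv2d(inplanes, planes, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(planes)
        self.conv2 = Conv2d(planes, planes, 3, stride=stride, padding=1,
                            bias=False, rng=rng)
        self.bn2 = BatchNorm2d(planes)
        self.conv3 = Conv2d(planes, out, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(out)
        if stride != 1 or inplanes != out:
            self.down = Sequential(
                Conv2d(inplanes, out, 1, stride=stride, bias=False, rng=rng),
                BatchNorm2d(out))
        else:
            self.down = None

    def forward(self, x):
        idt = x if self.down is None else self.down(x)
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        return (y + idt).relu()


def _resnet50(num_classes: int, rng) -> Module:
    layers: list[Module] = [
        Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng),
        BatchNorm2d(64), ReLU(), MaxPool2d(3, 2, 1)]
    inplanes = 64
    for planes, blocks, stride in [(64, 3, 1), (128, 4, 2),
                                   (256, 6, 2), (512, 3, 2)]:
        for b in range(blocks):
            layers.append(_Bottleneck(inplanes, planes,
                                      stride if b == 0 else 1, rng))
            inplanes = planes * _Bottleneck.expansion
    model = Sequential(*layers)

    class _ResNet(Module):
        def __init__(self):
            super().__init__()
            self.features = model
            self.fc = Linear(2048, num_classes, rng=rng)

        def forward(self, x):
            return self.fc(global_avg_pool(self.features(x)))

    return _ResNet()


class _InvertedResidual(Module):
    def __init__(self, inp, oup, stride, t, rng):
        super().__init__()
        hidden = int(round(inp * t))
        self.use_res = stride == 1 and inp == oup
        seq: list[Module] = []
        if t != 1:
            seq += [Conv2d(inp, hidden, 1, bias=False, rng=rng),
                    BatchNorm2d(hidden), ReLU()]
        seq += [Conv2d(hidden, hidden, 3, stride=stride, padding=1,
                       groups=hidden, bias=False, rng=rng),
                BatchNorm2d(hidden), ReLU(),
                Conv2d(hidden, oup, 1, bias=False, rng=rng),
                BatchNorm2d(oup)]
        self.block = Sequential(*seq)

    def forward(self, x):
        y = self.block(x)
        return x + y if self.use_res else y


def _mobilenet_v2(num_classes: int, rng) -> Module:
    settings = [(1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
                (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1)]
    layers: list[Module] = [Conv2d(3, 32, 3, stride=2, padding=1, bias=False,
                                   rng=rng), BatchNorm2d(32), ReLU()]
    in_ch = 32
    for t, c, n, s in settings:
        for i in range(n):
            layers.append(_InvertedResidual(in_ch, c, s if i == 0 else 1,
                                            t, rng))
            in_ch = c
    layers += [Conv2d(in_ch, 1280, 1, bias=False, rng=rng),
               BatchNorm2d(1280), ReLU()]
    features = Sequential(*layers)

    class _MobileNetV2(Module):
        def __init__(self):
            super().__init__()
            self.features = features
            self.classifier = Linear(1280, num_classes, rng=rng)

        def forward(self, x):
            return self.classifier(global_avg_pool(self.features(x)))

    return _MobileNetV2()


class _ViT(Module):
    def __init__(self, num_classes, rng, dim=768, depth=12, heads=12,
                 patch=16, image=224):
        super().__init__()
        n = (image // patch) ** 2
        self.patch_embed = Conv2d(3, dim, patch, stride=patch, bias=True,
                                  rng=rng)
        self.cls_token = Parameter(np.zeros((1, 1, dim), np.float32))
        self.pos = Parameter(0.02 * rng.standard_normal((1, n + 1, dim)))
        self.encoder = Sequential(*[EncoderLayer(dim, heads, 4.0, rng=rng)
                                    for _ in range(depth)])
        self.norm = LayerNorm(dim)
        self.head = Linear(dim, num_classes, rng=rng)
        self.dim = dim

    def forward(self, x):
        B = x.shape[0]
        y = self.patch_embed(x)                       # (B, D, h, w)
        D, h, w = y.shape[1:]
        tokens = y.reshape(B, D, h * w).transpose(0, 2, 1)
        cls = Tensor(np.zeros((B, 1, D), np.float32)) + self.cls_token
        tokens = concat([cls, tokens], axis=1) + self.pos
        tokens = self.norm(self.encoder(tokens))
        cls_out = tokens.reshape(B, h * w + 1, D)[:, 0]
        return self.head(cls_out)


BASELINES = ("vgg16", "resnet50", "vit_b16", "mobilenet_v2")


def build_baseline(name: str, num_classes: int = 2, seed: int = 0) -> Module:
    """Standard published architecture with its head resized to
    `num_classes` outputs."""
    rng = np.random.default_rng(seed)
    if name == "vgg16":
        return _vgg16(num_classes, rng)
    if name == "resnet50":
        return _resnet50(num_classes, rng)
    if name == "mobilenet_v2":
        return _mobilenet_v2(num_classes, rng)
    if name == "vit_b16":
        return _ViT(num_classes, rng)
    raise ValueError(f"unknown baseline {name!r}; choose from {BASELINES}")


def params_millions(model: Module) -> float:
    """Parameter count in millions, rounded to 3 decimals."""
    return round(count_parameters(model) / 1e6, 3)
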