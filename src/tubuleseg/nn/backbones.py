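"""Encoder backbones for the asymmetric U-Net variants.

Every encoder exposes ``feature_channels`` (five ints) and ``forward`` returning
five feature maps at strides 2, 4, 8, 16 and 32 relative to the input — the tap
points the decoder's skip connections attach to.  The tap at each stride is the
last feature map computed at that resolution; for backbones whose stem is the
only stride-2 computation, the post-stem pre-pool activation is used.

``basic`` is the classic U-Net contracting path (two 3x3 convolutions + ReLU
followed by 2x2 max pooling per stage).  ``tiny`` is the same layout at widths
small enough to train in seconds on a CPU.  ``resnet34``, ``densenet161`` and
``efficientnetb3`` follow the published block structure and channel widths of
the corresponding classification networks (batch-norm variants, randomly
initialised; ImageNet weights are not bundled).
"""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .layers import (
    BatchNorm2d,
    Conv2d,
    DepthwiseConv2d,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
)
from .tensor import Tensor


# --------------------------------------------------------------------- basic
class DoubleConv(Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.block = Sequential(
            Conv2d(in_ch, out_ch, 3, padding=1, rng=rng),
            ReLU(),
            Conv2d(out_ch, out_ch, 3, padding=1, rng=rng),
            ReLU(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)


class UNetEncoder(Module):
    """Plain convolutional contracting path (conv-conv-pool per stage)."""

    def __init__(self, channels: tuple[int, ...], rng: np.random.Generator):
        super().__init__()
        if len(channels) != 5:
            raise ValueError("encoder needs exactly 5 stage widths")
        self.feature_channels = list(channels)
        ins = [3] + list(channels[:-1])
        self.stages = [DoubleConv(i, o, rng) for i, o in zip(ins, channels)]
        self.pool = MaxPool2d(2, 2)

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = []
        for stage in self.stages:
            x = self.pool(stage(x))
            feats.append(x)
        return feats


# -------------------------------------------------------------------- resnet
class ResidualBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = F.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        identity = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return F.relu(F.add(out, identity))


class ResNet34Encoder(Module):
    feature_channels = [64, 64, 128, 256, 512]

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.stem_conv = Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(64)
        self.pool = MaxPool2d(3, 2, 1)
        cfg = [(64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)]
        self.layers = []
        in_ch = 64
        for out_ch, n_blocks, stride in cfg:
            blocks = []
            for b in range(n_blocks):
                blocks.append(ResidualBlock(in_ch, out_ch, stride if b == 0 else 1, rng))
                in_ch = out_ch
            self.layers.append(Sequential(*blocks))

    def forward(self, x: Tensor) -> list[Tensor]:
        f1 = F.relu(self.stem_bn(self.stem_conv(x)))  # stride 2
        x = self.pool(f1)
        f2 = self.layers[0](x)  # stride 4
        f3 = self.layers[1](f2)  # stride 8
        f4 = self.layers[2](f3)  # stride 16
        f5 = self.layers[3](f4)  # stride 32
        return [f1, f2, f3, f4, f5]


# ------------------------------------------------------------------ densenet
class DenseLayer(Module):
    def __init__(self, in_ch: int, growth: int, bn_size: int, rng: np.random.Generator):
        super().__init__()
        mid = bn_size * growth
        self.bn1 = BatchNorm2d(in_ch)
        self.conv1 = Conv2d(in_ch, mid, 1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(mid)
        self.conv2 = Conv2d(mid, growth, 3, padding=1, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        out = self.conv1(F.relu(self.bn1(x)))
        out = self.conv2(F.relu(self.bn2(out)))
        return F.concat([x, out], axis=1)


class Transition(Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.bn = BatchNorm2d(in_ch)
        self.conv = Conv2d(in_ch, out_ch, 1, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return F.avgpool2x2(self.conv(F.relu(self.bn(x))))


class DenseNet161Encoder(Module):
    feature_channels = [96, 384, 768, 2112, 2208]

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        growth, bn_size, init = 48, 4, 96
        block_cfg = (6, 12, 36, 24)
        self.stem_conv = Conv2d(3, init, 7, stride=2, padding=3, bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(init)
        self.pool = MaxPool2d(3, 2, 1)
        self.blocks = []
        self.transitions = []
        ch = init
        for i, n_layers in enumerate(block_cfg):
            layers = []
            for _ in range(n_layers):
                layers.append(DenseLayer(ch, growth, bn_size, rng))
                ch += growth
            self.blocks.append(Sequential(*layers))
            if i < len(block_cfg) - 1:
                self.transitions.append(Transition(ch, ch // 2, rng))
                ch //= 2
        self.final_bn = BatchNorm2d(ch)

    def forward(self, x: Tensor) -> list[Tensor]:
        f1 = F.relu(self.stem_bn(self.stem_conv(x)))  # stride 2
        x = self.pool(f1)
        f2 = self.blocks[0](x)  # stride 4
        x = self.transitions[0](f2)
        f3 = self.blocks[1](x)  # stride 8
        x = self.transitions[1](f3)
        f4 = self.blocks[2](x)  # stride 16
        x = self.transitions[2](f4)
        f5 = F.relu(self.final_bn(self.blocks[3](x)))  # stride 32
        return [f1, f2, f3, f4, f5]


# -------------------------------------------------------------- efficientnet
def _round_filters(c: int, width_mult: float, divisor: int = 8) -> int:
    c *= width_mult
    new_c = max(divisor, int(c + divisor / 2) // divisor * divisor)
    if new_c < 0.9 * c:
        new_c += divisor
    return new_c


def _round_repeats(r: int, depth_mult: float) -> int:
    return int(math.ceil(r * depth_mult))


class SqueezeExcite(Module):
    def __init__(self, channels: int, reduced: int, rng: np.random.Generator):
        super().__init__()
        self.reduce = Conv2d(channels, reduced, 1, rng=rng)
        self.expand = Conv2d(reduced, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = F.global_avg_pool(x)
        s = F.silu(self.reduce(s))
        s = F.sigmoid(self.expand(s))
        return F.mul(x, s)


class MBConv(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        expand: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        mid = in_ch * expand
        self.use_residual = stride == 1 and in_ch == out_ch
        if expand != 1:
            self.expand_conv = Conv2d(in_ch, mid, 1, bias=False, rng=rng)
            self.expand_bn = BatchNorm2d(mid)
        else:
            self.expand_conv = None
            self.expand_bn = None
        self.dw = DepthwiseConv2d(mid, kernel, stride=stride, padding=kernel // 2, rng=rng)
        self.dw_bn = BatchNorm2d(mid)
        self.se = SqueezeExcite(mid, max(1, in_ch // 4), rng)
        self.project = Conv2d(mid, out_ch, 1, bias=False, rng=rng)
        self.project_bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        out = x
        if self.expand_conv is not None:
            out = F.silu(self.expand_bn(self.expand_conv(out)))
        out = F.silu(self.dw_bn(self.dw(out)))
        out = self.se(out)
        out = self.project_bn(self.project(out))
        if self.use_residual:
            out = F.add(out, x)
        return out


class EfficientNetB3Encoder(Module):
    """EfficientNet-B3 feature hierarchy (width x1.2, depth x1.4 over B0)."""

    WIDTH, DEPTH = 1.2, 1.4
    # B0 stage settings: (expand, out_channels, repeats, stride, kernel)
    B0_STAGES = [
        (1, 16, 1, 1, 3),
        (6, 24, 2, 2, 3),
        (6, 40, 2, 2, 5),
        (6, 80, 3, 2, 3),
        (6, 112, 3, 1, 5),
        (6, 192, 4, 2, 5),
        (6, 320, 1, 1, 3),
    ]

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        stem_ch = _round_filters(32, self.WIDTH)
        self.stem_conv = Conv2d(3, stem_ch, 3, stride=2, padding=1, bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(stem_ch)
        self.stages = []
        stage_out = []
        in_ch = stem_ch
        for expand, c, r, s, k in self.B0_STAGES:
            out_ch = _round_filters(c, self.WIDTH)
            blocks = []
            for b in range(_round_repeats(r, self.DEPTH)):
                blocks.append(MBConv(in_ch, out_ch, expand, k, s if b == 0 else 1, rng))
                in_ch = out_ch
            self.stages.append(Sequential(*blocks))
            stage_out.append(out_ch)
        # last feature map at each stride: stages 1,2,3,5,7 end at strides 2,4,8,16,32
        self._tap_after = {0: 0, 1: 1, 2: 2, 4: 3, 6: 4}
        self.feature_channels = [stage_out[i] for i in (0, 1, 2, 4, 6)]

    def forward(self, x: Tensor) -> list[Tensor]:
        x = F.silu(self.stem_bn(self.stem_conv(x)))
        feats: list[Tensor] = [None] * 5
        for i, stage in enumerate(self.stages):
            x = stage(x)
            if i in self._tap_after:
                feats[self._tap_after[i]] = x
        return feats


# ------------------------------------------------------------------ registry
ENCODER_REGISTRY = {
    "basic": lambda rng, channels=None: UNetEncoder(tuple(channels or (64, 128, 256, 512, 1024)), rng),
    "tiny": lambda rng, channels=None: UNetEncoder(tuple(channels or (8, 16, 32, 32, 32)), rng),
    "resnet34": lambda rng, channels=None: ResNet34Encoder(rng),
    "densenet161": lambda rng, channels=None: DenseNet161Encoder(rng),
    "efficientnetb3": lambda rng, channels=None: EfficientNetB3Encoder(rng),
}
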