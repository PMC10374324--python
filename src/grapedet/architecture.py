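"""YOLO v4+ detector: SAM-CSPDarkNet-53 backbone, SPP, weighted PAN+ neck.

The backbone is a cross-stage-partial DarkNet with stage repeats
(1, 2, 8, 8, 4); every stage's merged output is refined by the parameter-free
SimAM block.  For a 608x608 input the three exported pyramid levels are
P3 = 76x76x256, P4 = 38x38x512 and P5 = 19x19x1024 (before the neck).

The neck applies spatial pyramid pooling (kernels 5/9/13) on P5 and a
path-aggregation network whose fusion nodes carry learnable scalar weights
normalized with the fast-normalized rule w_i = relu(r_i) / (sum_j relu(r_j) + eps).
The bottom-up P4 node is the three-input jump connection

    P4_out = ConvGroup(w0 * P4'' + w1 * Downsample(P3_out) + w2 * P4)

with ConvGroup a 3x3 then 1x1 standard convolution.  Three YOLO heads emit
3 * (5 + num_classes) channels each.

Backbone conv blocks use Mish (CBM); neck and head blocks use LeakyReLU 0.1
(CBL).  ``width_mult`` scales every channel width, giving the tiny
configurations used for CPU-scale training tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import ConvBlock, Module, Parameter, Tensor
from .simam import SimAM, SimAMConfig

__all__ = [
    "ArchitectureSpec", "FusionNode", "fast_normalized_fusion", "mish",
    "CSPStage", "Backbone", "SPP", "PANPlus", "YoloHead", "YoloV4Plus", "build_model",
]

BASE_CHANNELS = (32, 64, 128, 256, 512, 1024)


def mish(x):
    """Mish activation ``x * tanh(ln(1 + e^x))``; works on arrays and tensors."""
    return nn.mish(x)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Static description of one detector instantiation."""

    input_size: int = 608
    num_classes: int = 1
    stage_repeats: tuple[int, ...] = (1, 2, 8, 8, 4)
    attention: bool = True
    # per-stage SimAM mask (the literal reading of the backbone table leaves
    # stage 3 bare; the default refines all five stages)
    attention_stages: tuple[bool, ...] = (True, True, True, True, True)
    width_mult: float = 1.0
    simam_lam: float = 1e-4

    def __post_init__(self) -> None:
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be a multiple of 32")
        if len(self.stage_repeats) != 5:
            raise ValueError("exactly five backbone stages are required")

    def channels(self) -> tuple[int, ...]:
        return tuple(max(2, int(round(c * self.width_mult))) for c in BASE_CHANNELS)

    @property
    def head_channels(self) -> int:
        return 3 * (5 + self.num_classes)

    @property
    def strides(self) -> tuple[int, int, int]:
        return (8, 16, 32)

    def grid_sizes(self) -> tuple[int, int, int]:
        return tuple(self.input_size // s for s in self.strides)


class FusionNode(Module):
    """Weighted feature merge with fast-normalized non-negative weights."""

    def __init__(self, n_inputs: int, epsilon: float = 1e-4):
        super().__init__()
        self.raw_weights = Parameter(np.ones(n_inputs))
        self.epsilon = epsilon

    def normalized_weights(self) -> Tensor:
        w = nn.relu(self.raw_weights)
        return w / (w.sum() + self.epsilon)

    def forward(self, inputs: list[Tensor]) -> Tensor:
        if len(inputs) != self.raw_weights.size:
            raise ValueError(f"expected {self.raw_weights.size} inputs, got {len(inputs)}")
        shapes = {tuple(t.shape) for t in inputs}
        if len(shapes) != 1:
            raise ValueError(f"fusion inputs must share a shape, got {sorted(shapes)}")
        w = self.normalized_weights()
        out = w[0] * inputs[0]
        for i, t in enumerate(inputs[1:], start=1):
            out = out + w[i] * t
        return out


def fast_normalized_fusion(inputs: list[Tensor], node: FusionNode) -> Tensor:
    """Functional form of :class:`FusionNode`."""
    return node(inputs)


class Resblock(Module):
    def __init__(self, ch: int, hidden: int, rng):
        super().__init__()
        self.conv1 = ConvBlock(ch, hidden, 1, act="mish", rng=rng)
        self.conv2 = ConvBlock(hidden, ch, 3, act="mish", rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.conv2(self.conv1(x))


class CSPStage(Module):
    """Downsample + cross-stage-partial residual stack + SimAM refinement."""

    def __init__(self, in_ch: int, out_ch: int, n_blocks: int, first: bool,
                 attention: bool, lam: float, rng):
        super().__init__()
        part = out_ch if first else out_ch // 2
        hidden = part // 2 if first else part
        self.down = ConvBlock(in_ch, out_ch, 3, stride=2, act="mish", rng=rng)
        self.split = ConvBlock(out_ch, part, 1, act="mish", rng=rng)
        self.bypass = ConvBlock(out_ch, part, 1, act="mish", rng=rng)
        self.blocks = [Resblock(part, hidden, rng) for _ in range(n_blocks)]
        self.post = ConvBlock(part, part, 1, act="mish", rng=rng)
        self.merge = ConvBlock(2 * part, out_ch, 1, act="mish", rng=rng)
        self.attention = SimAM(SimAMConfig(lam)) if attention else nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        x = self.down(x)
        main = self.split(x)
        for b in self.blocks:
            main = b(main)
        main = self.post(main)
        out = self.merge(nn.concat([main, self.bypass(x)], axis=1))
        return self.attention(out)


class Backbone(Module):
    """SAM-CSPDarkNet: stem conv + five CSP stages, exporting stages 3-5."""

    def __init__(self, spec: ArchitectureSpec, rng):
        super().__init__()
        ch = spec.channels()
        self.stem = ConvBlock(3, ch[0], 3, act="mish", rng=rng)
        self.stages = [
            CSPStage(
                ch[i], ch[i + 1], spec.stage_repeats[i], first=(i == 0),
                attention=spec.attention and spec.attention_stages[i],
                lam=spec.simam_lam, rng=rng,
            )
            for i in range(5)
        ]

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        x = self.stem(x)
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats[2], feats[3], feats[4]  # P3, P4, P5


class SPP(Module):
    """Spatial pyramid pooling: identity + 5/9/13 same-padded max pools."""

    KERNELS = (5, 9, 13)

    def __init__(self, in_ch: int, rng):
        super().__init__()
        half = in_ch // 2
        self.pre = nn.Sequential(
            ConvBlock(in_ch, half, 1, act="leaky", rng=rng),
            ConvBlock(half, in_ch, 3, act="leaky", rng=rng),
            ConvBlock(in_ch, half, 1, act="leaky", rng=rng),
        )
        self.post = nn.Sequential(
            ConvBlock(4 * half, half, 1, act="leaky", rng=rng),
            ConvBlock(half, in_ch, 3, act="leaky", rng=rng),
            ConvBlock(in_ch, half, 1, act="leaky", rng=rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        x = self.pre(x)
        pools = [x] + [nn.maxpool_same(x, k) for k in self.KERNELS]
        return self.post(nn.concat(pools, axis=1))


def _five_convs(ch: int, rng) -> nn.Sequential:
    return nn.Sequential(
        ConvBlock(ch, ch, 1, act="leaky", rng=rng),
        ConvBlock(ch, 2 * ch, 3, act="leaky", rng=rng),
        ConvBlock(2 * ch, ch, 1, act="leaky", rng=rng),
        ConvBlock(ch, 2 * ch, 3, act="leaky", rng=rng),
        ConvBlock(2 * ch, ch, 1, act="leaky", rng=rng),
    )


class PANPlus(Module):
    """Top-down then bottom-up aggregation with weighted fusion nodes."""

    def __init__(self, spec: ArchitectureSpec, rng):
        super().__init__()
        ch = spec.channels()
        c3, c4, c5 = ch[3], ch[4], ch[5]   # 256, 512, 1024 at full width
        h4, h3 = c4 // 2, c3 // 2          # 256, 128
        self.p5_up = ConvBlock(c5 // 2, h4, 1, act="leaky", rng=rng)
        self.p4_align = ConvBlock(c4, h4, 1, act="leaky", rng=rng)
        self.fuse4_td = FusionNode(2)
        self.five4 = _five_convs(h4, rng)
        self.p4_up = ConvBlock(h4, h3, 1, act="leaky", rng=rng)
        self.p3_align = ConvBlock(c3, h3, 1, act="leaky", rng=rng)
        self.fuse3_td = FusionNode(2)
        self.five3 = _five_convs(h3, rng)
        self.down3 = ConvBlock(h3, h4, 3, stride=2, act="leaky", rng=rng)
        self.fuse4_bu = FusionNode(3)
        self.group4 = nn.Sequential(
            ConvBlock(h4, 2 * h4, 3, act="leaky", rng=rng),
            ConvBlock(2 * h4, h4, 1, act="leaky", rng=rng),
        )
        self.down4 = ConvBlock(h4, c5 // 2, 3, stride=2, act="leaky", rng=rng)
        self.group5 = nn.Sequential(
            ConvBlock(c5, c5, 3, act="leaky", rng=rng),
            ConvBlock(c5, c5 // 2, 1, act="leaky", rng=rng),
        )

    def forward(self, p3: Tensor, p4: Tensor, p5: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        # p5 arrives SPP-processed at c5 // 2 channels
        p4a = self.p4_align(p4)
        p4_mid = self.five4(self.fuse4_td([nn.upsample2x(self.p5_up(p5)), p4a]))  # P4''
        p3a = self.p3_align(p3)
        p3_out = self.five3(self.fuse3_td([nn.upsample2x(self.p4_up(p4_mid)), p3a]))
        p4_out = self.group4(self.fuse4_bu([p4_mid, self.down3(p3_out), p4a]))
        p5_out = self.group5(nn.concat([self.down4(p4_out), p5], axis=1))
        return p3_out, p4_out, p5_out


class YoloHead(Module):
    """3x3 CBL expansion + linear 1x1 projection to 3 * (5 + C) channels."""

    def __init__(self, in_ch: int, num_classes: int, rng):
        super().__init__()
        self.expand = ConvBlock(in_ch, 2 * in_ch, 3, act="leaky", rng=rng)
        self.project = nn.Conv2d(2 * in_ch, 3 * (5 + num_classes), 1, rng=rng)
        # small-offset init: raw predictions start near zero, so decoded boxes
        # start at their anchors and the box regression is well-conditioned
        self.project.weight.data *= 0.08
        self.project.bias.data[:] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        return self.project(self.expand(x))


class YoloV4Plus(Module):
    """Full detector; forward returns the three raw prediction grids."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        ch = spec.channels()
        self.backbone = Backbone(spec, rng)
        self.spp = SPP(ch[5], rng)
        self.neck = PANPlus(spec, rng)
        self.heads = [
            YoloHead(ch[3] // 2, spec.num_classes, rng),
            YoloHead(ch[4] // 2, spec.num_classes, rng),
            YoloHead(ch[5] // 2, spec.num_classes, rng),
        ]

    def backbone_parameters(self):
        return self.backbone.parameters()

    def forward(self, x) -> list[Tensor]:
        x = nn.as_tensor(x)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("input must be (N, 3, H, W)")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input spatial size must be a multiple of 32")
        if not self.training:
            # inference: skip graph construction so conv workspaces are freed
            with nn.no_grad():
                return self._forward(x)
        return self._forward(x)

    def _forward(self, x: Tensor) -> list[Tensor]:
        p3, p4, p5 = self.backbone(x)
        p5 = self.spp(p5)
        f3, f4, f5 = self.neck(p3, p4, p5)
        return [self.heads[0](f3), self.heads[1](f4), self.heads[2](f5)]


def build_model(spec: ArchitectureSpec, seed: int = 0) -> YoloV4Plus:
    return YoloV4Plus(spec, seed=seed)


def backbone_forward(image, spec: ArchitectureSpec, seed: int = 0):
    """Convenience: run a freshly initialized backbone, returning (P3, P4, P5)."""
    model = Backbone(spec, np.random.default_rng(seed)).eval()
    return model(nn.as_tensor(image))
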