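"""Dense convolutional patch encoder with multi-resolution feature taps,
plus architecture-analysis utilities (theoretical receptive field and exact
parameter counting).

The reference profile reproduces the DenseNet-121 topology — four dense
blocks of 6/12/24/16 bottleneck layers, growth rate 32, 64 stem channels —
with taps after transitions 1/2/3 at strides 8/16/32.  For a 375x375 patch
the tap resolutions are 47x47, 23x23 and 11x11 (floor-stride arithmetic);
the deepest features after block 4 are also 11x11.  A ``width_scale``
multiplier shrinks every channel count for desk-scale profiles while keeping
the topology and the stride arithmetic intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import BackboneConfig
from .nn import functional as F

__all__ = [
    "BlockFeatures",
    "DenseEncoder",
    "build_backbone",
    "densenet121_classifier",
    "receptive_field",
    "resnet18_layer_spec",
    "count_parameters",
    "tap_sizes",
]


@dataclass
class BlockFeatures:
    """Multi-resolution taps of one (batch of) encoded patch(es).

    b1/b2/b3 are the stride-8/16/32 taps feeding the proposal FPN and the
    layer projections; b4 is the deepest post-block-4 feature (same spatial
    size as b3) used by the local attention gate.
    """

    b1: nn.Tensor   # stride 8   (47x47 for a 375 patch)
    b2: nn.Tensor   # stride 16  (23x23)
    b3: nn.Tensor   # stride 32  (11x11)
    b4: nn.Tensor   # stride 32, post block 4 (11x11, deepest)

    @property
    def taps(self):
        return (self.b1, self.b2, self.b3)


class _DenseLayer(nn.Module):
    def __init__(self, c_in: int, growth: int, rng):
        super().__init__()
        inter = 4 * growth
        self.bn1 = nn.BatchNorm2d(c_in)
        self.conv1 = nn.Conv2d(c_in, inter, 1, rng)
        self.bn2 = nn.BatchNorm2d(inter)
        self.conv2 = nn.Conv2d(inter, growth, 3, rng, padding=1)

    def forward(self, x):
        y = self.conv1(self.bn1(x).relu())
        y = self.conv2(self.bn2(y).relu())
        return nn.concat([x, y], axis=1)


class _DenseBlock(nn.Module):
    def __init__(self, c_in: int, n_layers: int, growth: int, rng):
        super().__init__()
        self.layers = [_DenseLayer(c_in + i * growth, growth, rng)
                       for i in range(n_layers)]
        self.out_channels = c_in + n_layers * growth

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class _Transition(nn.Module):
    def __init__(self, c_in: int, rng):
        super().__init__()
        self.out_channels = c_in // 2
        self.bn = nn.BatchNorm2d(c_in)
        self.conv = nn.Conv2d(c_in, self.out_channels, 1, rng)

    def forward(self, x):
        return F.avg_pool2d(self.conv(self.bn(x).relu()), 2)


class DenseEncoder(nn.Module):
    """Four-block dense encoder; ``forward`` returns :class:`BlockFeatures`."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        g, c = cfg.growth, cfg.stem_channels
        self.cfg = cfg
        self.stem_conv = nn.Conv2d(cfg.in_channels, c, 7, rng, stride=2, padding=3)
        self.stem_bn = nn.BatchNorm2d(c)

        blocks, transitions = [], []
        for i, n_layers in enumerate(cfg.block_layer_counts):
            block = _DenseBlock(c, n_layers, g, rng)
            blocks.append(block)
            c = block.out_channels
            if i < 3:
                tr = _Transition(c, rng)
                transitions.append(tr)
                c = tr.out_channels
        self.blocks = blocks
        self.transitions = transitions
        self.final_bn = nn.BatchNorm2d(c)
        self.out_channels = c
        self.tap_channels = (transitions[0].out_channels,
                             transitions[1].out_channels,
                             transitions[2].out_channels)

    def forward(self, x: nn.Tensor) -> BlockFeatures:
        min_side = min(x.shape[2], x.shape[3])
        if min_side < 32:
            raise ValueError(f"patch side {min_side} below the total stride 32")
        x = F.max_pool2d(self.stem_bn(self.stem_conv(x)).relu(), 3, 2, 1)
        x = self.transitions[0](self.blocks[0](x))
        b1 = x                                    # stride 8
        x = self.transitions[1](self.blocks[1](x))
        b2 = x                                    # stride 16
        x = self.transitions[2](self.blocks[2](x))
        b3 = x                                    # stride 32
        x = self.final_bn(self.blocks[3](x)).relu()
        return BlockFeatures(b1=b1, b2=b2, b3=b3, b4=x)


def build_backbone(cfg: BackboneConfig, rng: np.random.Generator) -> DenseEncoder:
    return DenseEncoder(cfg, rng)


class densenet121_classifier(nn.Module):
    """The original 121-layer image classifier (3-channel input, 1000-way
    head) built from the same encoder — used for parameter accounting."""

    def __init__(self, rng: np.random.Generator, num_classes: int = 1000):
        super().__init__()
        self.encoder = DenseEncoder(BackboneConfig(in_channels=3), rng)
        self.fc = nn.Linear(self.encoder.out_channels, num_classes, rng, bias=True)

    def forward(self, x):
        feats = self.encoder(x)
        pooled = feats.b4.mean(axis=(2, 3))
        return self.fc(pooled)


# ----------------------------------------------------------------------
# architecture analysis


def tap_sizes(side: int) -> tuple[int, int, int]:
    """Spatial side lengths of the three taps for a square input of
    ``side`` pixels, by floor-stride arithmetic."""
    s = (side + 2 * 3 - 7) // 2 + 1      # stem conv 7x7 s2 p3
    s = (s + 2 * 1 - 3) // 2 + 1         # stem maxpool 3x3 s2 p1
    t1 = s // 2                          # transition pools: floor halving
    t2 = t1 // 2
    t3 = t2 // 2
    return (t1, t2, t3)


def receptive_field(layer_spec: list[tuple[int, int]]) -> int:
    """Theoretical maximal-path receptive field of a (kernel, stride) chain:
    rf <- rf + (k-1)*jump; jump <- jump*stride."""
    if not layer_spec:
        raise ValueError("layer spec is empty")
    rf, jump = 1, 1
    for k, s in layer_spec:
        if k <= 0 or s <= 0:
            raise ValueError("kernel and stride must be positive")
        rf += (k - 1) * jump
        jump *= s
    return rf


def resnet18_layer_spec() -> list[tuple[int, int]]:
    """(kernel, stride) chain of the standard 18-layer residual network
    along its deepest path: 7x7/2 stem, 3x3/2 pool, then four stages of two
    basic blocks (two 3x3 convs each) with stride 2 entering stages 2-4."""
    spec = [(7, 2), (3, 2)]
    for stage in range(4):
        for block in range(2):
            first_stride = 2 if (stage > 0 and block == 0) else 1
            spec += [(3, first_stride), (3, 1)]
    return spec


def count_parameters(model: nn.Module) -> int:
    """Exact trainable-weight count."""
    return nn.count_trainable(model)
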