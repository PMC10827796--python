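"""Second stage: the classification branch and the localization autoencoder.

Classification:  Sm(Mlp(Avg(C3 o C3 o Max o C1)(z_x))) — a conv stack over
the stitched image-level features, global average pooling, a two-hidden-layer
(256, 256) perceptron and a 4-way softmax.  The predicted class is the
arg max of the softmax confidence (ties break to the lowest class index,
AB < OKC < DC < Normal).

Localization:  psi_hat = D(Concat(E(x); reduce(z_x))) — a strided conv
encoder E over the working image, fused at the bottleneck with the
1x1-channel-reduced z_x, decoded with skip aggregation from every encoder
level to a sigmoid heatmap at half the working resolution (750x375 in the
reference profile), thresholded at th_s (default 0.5) into the binary
segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import CLASSES, nn
from .config import GeometryConfig, ModelConfig
from .nn import functional as F

__all__ = ["ClassificationHead", "LocalizationHead", "Diagnosis",
           "threshold_heatmap", "predict_class"]


class ClassificationHead(nn.Module):
    def __init__(self, z_channels: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        c = cfg.attn_channels
        h1, h2 = cfg.mlp_hidden
        self.conv_in = nn.Conv2d(z_channels, c, 1, rng)
        self.conv_a = nn.Conv2d(c, c, 3, rng, padding=1)
        self.conv_b = nn.Conv2d(c, c, 3, rng, padding=1)
        self.fc1 = nn.Linear(c, h1, rng)
        self.fc2 = nn.Linear(h1, h2, rng)
        self.fc_out = nn.Linear(h2, len(CLASSES), rng)

    def forward(self, z_x: nn.Tensor) -> nn.Tensor:
        """Returns class logits (B, 4)."""
        x = F.max_pool2d(self.conv_in(z_x), 2)
        x = self.conv_a(x).relu()
        x = self.conv_b(x).relu()
        x = x.mean(axis=(2, 3))                      # global average pool
        x = self.fc1(x).relu()
        x = self.fc2(x).relu()
        logits = self.fc_out(x)
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("non-finite classification activations")
        return logits


class LocalizationHead(nn.Module):
    """Autoencoder branch with deep-layer skip aggregation in the decoder."""

    def __init__(self, z_channels: int, geometry: GeometryConfig,
                 cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        chans = cfg.loc_channels
        self.geometry = geometry
        self.reduce = nn.Conv2d(z_channels, cfg.zreduce_channels, 1, rng)
        self.enc_convs, self.enc_bns = [], []
        c_in = 1
        for c in chans:
            self.enc_convs.append(nn.Conv2d(c_in, c, 3, rng, stride=2, padding=1))
            self.enc_bns.append(nn.BatchNorm2d(c))
            c_in = c
        self.bottleneck = nn.Conv2d(chans[-1] + cfg.zreduce_channels, chans[-1],
                                    3, rng, padding=1)
        self.dec_convs, self.dec_bns = [], []
        c_prev = chans[-1]
        for c_skip in reversed(chans[:-1]):
            self.dec_convs.append(nn.Conv2d(c_prev + c_skip, c_skip, 3, rng,
                                            padding=1))
            self.dec_bns.append(nn.BatchNorm2d(c_skip))
            c_prev = c_skip
        self.out_conv = nn.Conv2d(chans[0], 1, 1, rng, bias=True)

    def forward(self, x_img: nn.Tensor, z_x: nn.Tensor) -> nn.Tensor:
        """``x_img``: working image (B, 1, H, W); returns the heatmap
        (B, 1, h', w') in [0, 1] at the configured seg resolution."""
        skips = []
        x = x_img
        for conv, bn in zip(self.enc_convs, self.enc_bns):
            x = bn(conv(x)).relu()
            skips.append(x)
        zr = self.reduce(z_x)
        zr = F.resize_nearest(zr, x.shape[2:])
        x = self.bottleneck(nn.concat([x, zr], axis=1)).relu()
        for conv, bn, skip in zip(self.dec_convs, self.dec_bns,
                                  reversed(skips[:-1])):
            up = F.resize_nearest(x, skip.shape[2:])
            x = bn(conv(nn.concat([up, skip], axis=1))).relu()
        psi = self.out_conv(x).sigmoid()
        sw, sh = self.geometry.seg_size
        if psi.shape[2:] != (sh, sw):
            raise ValueError(f"decoder output {psi.shape[2:]} does not match "
                             f"seg size {(sh, sw)}")
        return psi


def threshold_heatmap(psi: np.ndarray, th_s: float) -> np.ndarray:
    """Binary segmentation: pixels with heatmap value >= th_s."""
    if not 0.0 <= th_s <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    psi = np.asarray(psi)
    if psi.min() < -1e-6 or psi.max() > 1 + 1e-6:
        raise ValueError("heatmap values must lie in [0, 1]")
    return psi >= th_s


def predict_class(scores: np.ndarray) -> str:
    """Highest-confidence class; ties break to the lowest class index."""
    return CLASSES[int(np.argmax(scores))]


@dataclass
class Diagnosis:
    """Full prediction for one image."""
    class_scores: dict                    # class -> softmax confidence
    label: str                            # argmax class
    heatmap: np.ndarray                   # (h', w') in [0, 1]
    segmentation: np.ndarray              # bool (h', w')
    heatmap_ignorable: bool = False       # True when the class is Normal
    meta: dict = field(default_factory=dict)

    def validate(self) -> "Diagnosis":
        total = sum(self.class_scores.values())
        if abs(total - 1.0) > 1e-4:
            raise ValueError(f"class scores sum to {total}, expected 1")
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label}")
        if self.heatmap.shape != self.segmentation.shape:
            raise ValueError("heatmap / segmentation shape mismatch")
        return self
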