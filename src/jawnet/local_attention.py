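"""Patch-level (local) attention: FPN-style region proposals over the
multi-resolution taps, top-k proposal merging into a lesion-location heatmap,
and the gated patch representation.

For each cell ("anchor") of each tap, the proposal head predicts per-lesion-
class confidences, an objectness score, and box offsets for a set of
predefined box shapes; coarser taps propose larger boxes.  The top-k
proposals by objectness are merged by accumulating score-weighted soft box
masks on the deepest-tap grid and normalizing by the maximum, giving a
heatmap in [0, 1] that is differentiable with respect to the scores (the
normalization constant is treated as a stop-gradient).  The heatmap then
gates the deepest backbone features:

    h_i = (C3 o C3 o C1)( Sigm(Nrm(B4)) x psi_fpn )

with Nrm a per-channel spatial standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import BlockFeatures
from .nn import functional as F

__all__ = ["AnchorConfig", "ProposalSet", "RegionProposalFPN", "LocalAttention",
           "merge_proposals", "soft_box_coverage"]


@dataclass
class AnchorConfig:
    """Predefined box shapes: one scale per tap level x three aspect ratios."""
    ratios: tuple = ((1.0, 1.0), (2.0, 1.0), (1.0, 2.0))
    scale_per_stride: float = 4.0          # base box side = stride * this
    max_log_delta: float = 2.0             # clamp on predicted log-size offsets

    @property
    def n_shapes(self) -> int:
        return len(self.ratios)


@dataclass
class ProposalSet:
    """Scored boxes for one batch of patches.

    ``boxes`` (N, P, 4) are in patch pixels, clipped to the patch;
    ``objectness`` is kept as a graph tensor (N, P) so the merged heatmap
    stays differentiable with respect to the scores.
    """
    boxes: np.ndarray                       # (N, P, 4) float
    objectness: nn.Tensor                   # (N, P) in [0, 1]
    cls_scores: np.ndarray                  # (N, P, n_lesion_classes) in [0, 1]
    levels: np.ndarray                      # (P,) tap level of each proposal
    centers: np.ndarray = field(default=None)  # (P, 2) anchor centers, patch px

    @property
    def n_proposals(self) -> int:
        return self.boxes.shape[1]


class RegionProposalFPN(nn.Module):
    """Top-down feature pyramid with a shared proposal head per level."""

    def __init__(self, tap_channels: tuple[int, int, int], fpn_channels: int,
                 n_lesion_classes: int, patch_size: int,
                 rng: np.random.Generator, anchors: AnchorConfig | None = None):
        super().__init__()
        self.anchors = anchors or AnchorConfig()
        self.patch_size = patch_size
        self.n_cls = n_lesion_classes
        a = self.anchors.n_shapes
        self.laterals = [nn.Conv2d(c, fpn_channels, 1, rng) for c in tap_channels]
        self.smooths = [nn.Conv2d(fpn_channels, fpn_channels, 3, rng, padding=1)
                        for _ in tap_channels]
        self.head_conv = nn.Conv2d(fpn_channels, fpn_channels, 3, rng, padding=1)
        self.head_out = nn.Conv2d(fpn_channels, a * (n_lesion_classes + 1 + 4), 1,
                                  rng, bias=True)

    def forward(self, feats: BlockFeatures) -> ProposalSet:
        taps = feats.taps
        if any(t.data.size == 0 for t in taps):
            raise ValueError("empty features")
        # top-down pathway: coarse to fine
        p3 = self.laterals[2](taps[2])
        p2 = self.laterals[1](taps[1]) + F.resize_nearest(p3, taps[1].shape[2:])
        p1 = self.laterals[0](taps[0]) + F.resize_nearest(p2, taps[0].shape[2:])
        pyramid = [self.smooths[0](p1), self.smooths[1](p2), self.smooths[2](p3)]

        n = taps[0].shape[0]
        a = self.anchors.n_shapes
        obj_parts, box_list, cls_list, lvl_list, ctr_list = [], [], [], [], []
        for lvl, p in enumerate(pyramid):
            out = self.head_out(self.head_conv(p).relu())   # (n, a*(c+5), H, W)
            gh, gw = out.shape[2], out.shape[3]
            stride = self.patch_size / max(gh, gw)
            out = out.reshape(n, a, self.n_cls + 5, gh, gw)
            out = out.transpose((0, 3, 4, 1, 2)).reshape(n, gh * gw * a,
                                                         self.n_cls + 5)
            obj_parts.append(out[:, :, self.n_cls].sigmoid())
            cls_list.append(1.0 / (1.0 + np.exp(-out.data[:, :, :self.n_cls])))

            ys, xs = np.mgrid[0:gh, 0:gw].astype(np.float32)
            cxs = (xs + 0.5) * stride
            cys = (ys + 0.5) * stride
            centers = np.stack([cxs, cys], -1).reshape(gh * gw, 1, 2)
            centers = np.broadcast_to(centers, (gh * gw, a, 2)).reshape(-1, 2)
            base = stride * self.anchors.scale_per_stride
            shapes = np.array([(base * np.sqrt(rw / rh), base * np.sqrt(rh / rw))
                               for rw, rh in self.anchors.ratios], np.float32)
            deltas = out.data[:, :, self.n_cls + 1:]        # (n, L*a, 4) detached
            deltas = np.clip(deltas, -self.anchors.max_log_delta,
                             self.anchors.max_log_delta)
            wh = shapes[None, None, :, :] * np.exp(
                deltas.reshape(n, gh * gw, a, 4)[..., 2:4])
            ctr = centers.reshape(1, gh * gw, a, 2) \
                + deltas.reshape(n, gh * gw, a, 4)[..., 0:2] * base
            x0 = ctr[..., 0] - wh[..., 0] / 2
            y0 = ctr[..., 1] - wh[..., 1] / 2
            boxes = np.stack([x0, y0, x0 + wh[..., 0], y0 + wh[..., 1]], -1)
            boxes = np.clip(boxes, 0.0, self.patch_size).reshape(n, -1, 4)
            box_list.append(boxes)
            lvl_list.append(np.full(gh * gw * a, lvl, np.int32))
            ctr_list.append(centers)

        return ProposalSet(
            boxes=np.concatenate(box_list, axis=1),
            objectness=nn.concat(obj_parts, axis=1),
            cls_scores=np.concatenate(cls_list, axis=1),
            levels=np.concatenate(lvl_list),
            centers=np.concatenate(ctr_list, axis=0),
        )


def soft_box_coverage(boxes: np.ndarray, grid_hw: tuple[int, int],
                      patch_size: int) -> np.ndarray:
    """Fraction of each grid cell covered by each box: (P, gh*gw), values in
    [0, 1], separable interval overlap along each axis (soft box edges)."""
    gh, gw = grid_hw
    csx = patch_size / gw
    csy = patch_size / gh
    xs = np.arange(gw, dtype=np.float32) * csx
    ys = np.arange(gh, dtype=np.float32) * csy
    x0, y0, x1, y1 = (boxes[:, i][:, None] for i in range(4))
    covx = np.clip(np.minimum(x1, xs[None] + csx) - np.maximum(x0, xs[None]),
                   0.0, csx) / csx
    covy = np.clip(np.minimum(y1, ys[None] + csy) - np.maximum(y0, ys[None]),
                   0.0, csy) / csy
    return (covy[:, :, None] * covx[:, None, :]).reshape(boxes.shape[0], gh * gw)


def merge_proposals(proposals: ProposalSet, top_k: int,
                    grid_hw: tuple[int, int], patch_size: int) -> nn.Tensor:
    """Merge the top-k proposals by objectness into the local attention
    heatmap psi_fpn at the deepest-tap resolution: accumulate score-weighted
    soft box masks, then normalize by the (detached) maximum so values lie in
    [0, 1].  With zero usable proposals the map falls back to all ones
    (no attenuation), with a warning."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    n, p = proposals.objectness.shape
    gh, gw = grid_hw
    maps = []
    for i in range(n):
        obj = proposals.objectness[i]
        k = min(top_k, p)
        order = np.argsort(-obj.data, kind="stable")[:k]
        cov = soft_box_coverage(proposals.boxes[i][order], grid_hw, patch_size)
        psi_flat = obj[order].reshape(1, k) @ nn.Tensor(cov)     # (1, gh*gw)
        peak = float(psi_flat.data.max())
        if peak <= 1e-12:
            warnings.warn("no proposal covers the grid; uniform attention "
                          "fallback", stacklevel=2)
            maps.append(nn.Tensor(np.ones((1, 1, gh, gw), np.float32)))
        else:
            maps.append((psi_flat * (1.0 / peak)).reshape(1, 1, gh, gw))
    return nn.concat(maps, axis=0)                               # (n, 1, gh, gw)


class LocalAttention(nn.Module):
    """Gates the deepest backbone features with the local heatmap and
    projects them to the patch representation h_i."""

    def __init__(self, b4_channels: int, attn_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(b4_channels, attn_channels, 1, rng)
        self.conv2 = nn.Conv2d(attn_channels, attn_channels, 3, rng, padding=1)
        self.conv3 = nn.Conv2d(attn_channels, attn_channels, 3, rng, padding=1)

    @staticmethod
    def gate(b4: nn.Tensor, psi: nn.Tensor) -> nn.Tensor:
        """Sigm(Nrm(B4)) x psi — bounded in [0, 1] before the convolutions."""
        if psi.shape[2:] != b4.shape[2:]:
            raise ValueError(f"attention map {psi.shape} does not match "
                             f"features {b4.shape}")
        mu = b4.mean(axis=(2, 3), keepdims=True)
        var = ((b4 - mu) ** 2.0).mean(axis=(2, 3), keepdims=True)
        normed = (b4 - mu) * ((var + 1e-5) ** -0.5)
        return normed.sigmoid() * psi

    def forward(self, b4: nn.Tensor, psi: nn.Tensor) -> nn.Tensor:
        x = self.gate(b4, psi)
        x = self.conv1(x).relu()
        x = self.conv2(x).relu()
        return self.conv3(x)
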