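"""The assembled two-stage network and the end-to-end ``diagnose`` entry
point.

Stage 1 (per patch): dense encoder -> FPN proposals -> merged local attention
heatmap -> gated patch representation h_i; all patch representations are
aggregated into the shared global map h which reciprocally calibrates the
per-patch multi-layer projections into z_i.

Stage 2 (whole image): the z_i are stitched back into the image-level map
z_x, which feeds both the classification head and (channel-reduced, fused
with the image autoencoder) the localization head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import CLASSES, nn
from .backbone import BlockFeatures, DenseEncoder
from .config import RunConfig
from .global_attention import GlobalAttention, reshape_to_image
from .heads import (ClassificationHead, Diagnosis, LocalizationHead,
                    predict_class, threshold_heatmap)
from .local_attention import LocalAttention, RegionProposalFPN, merge_proposals
from .nn import functional as F
from .phantom import RadiographSample
from .preprocess import preprocess_image

__all__ = ["TwoStageNet", "ForwardOutputs", "build_model", "diagnose"]


@dataclass
class ForwardOutputs:
    logits: nn.Tensor          # (B, 4)
    heatmap: nn.Tensor         # (B, 1, h', w')
    z_x: nn.Tensor             # (B, 3*attn, rows*g, cols*g)
    global_map: nn.Tensor      # (B, attn, g, g)
    psi_fpn: nn.Tensor         # (B*K, 1, g, g)
    patch_feats: BlockFeatures


class TwoStageNet(nn.Module):
    def __init__(self, cfg: RunConfig, rng: np.random.Generator,
                 backbone: DenseEncoder | None = None):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.backbone = backbone or DenseEncoder(cfg.backbone, rng)
        self.backbone_frozen = False
        tap_ch = self.backbone.tap_channels
        self.fpn = RegionProposalFPN(tap_ch, cfg.model.fpn_channels,
                                     cfg.model.n_lesion_classes,
                                     cfg.geometry.patch_size, rng)
        self.local_attention = LocalAttention(self.backbone.out_channels,
                                              cfg.model.attn_channels, rng)
        self.global_attention = GlobalAttention(cfg.geometry.n_patches,
                                                cfg.model.attn_channels,
                                                tap_ch, rng)
        z_channels = 3 * cfg.model.attn_channels
        self.cls_head = ClassificationHead(z_channels, cfg.model, rng)
        self.loc_head = LocalizationHead(z_channels, cfg.geometry, cfg.model, rng)

    # -- freezing ------------------------------------------------------
    def freeze_backbone(self) -> None:
        """Fix every backbone parameter and statistic (step-2 contract)."""
        for p in self.backbone.parameters():
            p.requires_grad = False
        self.backbone.eval()
        self.backbone_frozen = True

    def train(self, mode: bool = True):
        super().train(mode)
        if self.backbone_frozen:
            self.backbone.eval()
        return self

    # -- forward ---------------------------------------------------------
    def _split_patches(self, x: nn.Tensor) -> nn.Tensor:
        """(B, 1, H, W) -> (B*K, 1, p, p), sample-major, row-major patches."""
        n_cols, n_rows = self.cfg.geometry.grid
        p = self.cfg.geometry.patch_size
        b = x.shape[0]
        tiles = [x[:, :, r * p:(r + 1) * p, c * p:(c + 1) * p]
                 for r in range(n_rows) for c in range(n_cols)]
        stacked = nn.concat(tiles, axis=0)                   # (K*B, 1, p, p)
        k = n_rows * n_cols
        return stacked.reshape(k, b, 1, p, p).transpose((1, 0, 2, 3, 4)) \
                      .reshape(b * k, 1, p, p)

    def forward(self, x: nn.Tensor) -> ForwardOutputs:
        geo = self.cfg.geometry
        w, h = geo.working_size
        if x.shape[2:] != (h, w):
            raise ValueError(f"input {x.shape[2:]} != working size {(h, w)}")
        patches = self._split_patches(x)
        feats = self.backbone(patches)
        if self.backbone_frozen:
            feats = BlockFeatures(*(t.detach() for t in
                                    (feats.b1, feats.b2, feats.b3, feats.b4)))

        grid_hw = feats.b3.shape[2:]
        proposals = self.fpn(feats)
        psi = merge_proposals(proposals, self.cfg.model.top_k, grid_hw,
                              geo.patch_size)
        h_i = self.local_attention(feats.b4, psi)

        g_map = self.global_attention.build_global_map(h_i)
        z_layers = self.global_attention.project_layers(feats)
        z_i = self.global_attention.attend_patch(z_layers, g_map)
        z_x = reshape_to_image(z_i, geo.grid)

        logits = self.cls_head(z_x)
        heatmap = self.loc_head(x, z_x)
        return ForwardOutputs(logits=logits, heatmap=heatmap, z_x=z_x,
                              global_map=g_map, psi_fpn=psi, patch_feats=feats)


def build_model(cfg: RunConfig, seed: int | None = None) -> TwoStageNet:
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return TwoStageNet(cfg, rng)


def diagnose(raw_image: np.ndarray | RadiographSample, model: TwoStageNet
             ) -> Diagnosis:
    """Full pipeline on one raw image: preprocess -> patches -> stage 1 ->
    stage 2 -> class scores, heatmap, thresholded segmentation.  The heatmap
    of a Normal prediction is retained but flagged ignorable."""
    img = raw_image.image if isinstance(raw_image, RadiographSample) else raw_image
    img = np.asarray(img, np.float32)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale image")
    was_training = model.training
    model.eval()
    try:
        working = preprocess_image(img, model.cfg.geometry)
        x = nn.Tensor(working[None, None])
        with nn.no_grad():
            out = model(x)
        probs = F.softmax(out.logits, axis=1).data[0]
        label = predict_class(probs)
        heatmap = out.heatmap.data[0, 0]
        seg = threshold_heatmap(heatmap, model.cfg.geometry.seg_threshold)
    finally:
        model.train(was_training)
    return Diagnosis(
        class_scores={c: float(p) for c, p in zip(CLASSES, probs)},
        label=label, heatmap=heatmap, segmentation=seg,
        heatmap_ignorable=(label == "Normal"),
    ).validate()
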