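"""Inter-patch (global) attention: the shared global map built from all
patch representations, the reciprocal calibration of per-patch multi-layer
features, and the stitching of patch features into the image-level map.

    h   = (C3 o C3 o C1)( Concat(h_1; ...; h_K) )        -- shared across patches
    z_i = Concat(z_{i,1}; z_{i,2}; z_{i,3}) x h          -- h tiled over groups
    z_x = Reshape(z_1; ...; z_K)                          -- patch-grid stitching

where z_{i,l} = (ReLU o BN o C3)(B_l(x_i)) with B_l average-pooled down to
the deepest-tap resolution.  Because h is computed from every patch and
multiplied back into every patch, gradients (and perturbations) of one patch
reach the representation of all others — the mutual-influence mechanism.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .backbone import BlockFeatures
from .nn import functional as F

__all__ = ["GlobalAttention", "reshape_to_image"]


class GlobalAttention(nn.Module):
    def __init__(self, n_patches: int, attn_channels: int,
                 tap_channels: tuple[int, int, int], rng: np.random.Generator):
        super().__init__()
        self.k = n_patches
        self.attn_channels = attn_channels
        c = attn_channels
        self.gconv1 = nn.Conv2d(n_patches * c, c, 1, rng)
        self.gconv2 = nn.Conv2d(c, c, 3, rng, padding=1)
        # near-identity gate initialisation: h ~ 1 at the start of training,
        # so z_i = z x h begins as the plain layer concatenation and the
        # calibration learns to deviate from identity (FiLM-style init)
        self.gconv3 = nn.Conv2d(c, c, 3, rng, padding=1, bias=True)
        self.gconv3.weight.data *= 0.1
        self.gconv3.bias.data[:] = 1.0
        self.proj_convs = [nn.Conv2d(tc, c, 3, rng, padding=1)
                           for tc in tap_channels]
        self.proj_bns = [nn.BatchNorm2d(c) for _ in tap_channels]

    # -- Eq: shared global map -----------------------------------------
    def build_global_map(self, h_patches: nn.Tensor) -> nn.Tensor:
        """``h_patches``: (B*K, C, g, g) patch features in sample-major
        order -> shared map (B, C, g, g)."""
        bk, c, gh, gw = h_patches.shape
        if bk % self.k:
            raise ValueError(f"batch {bk} not divisible by K={self.k}")
        b = bk // self.k
        stacked = h_patches.reshape(b, self.k * c, gh, gw)
        g = self.gconv1(stacked).relu()
        g = self.gconv2(g).relu()
        return self.gconv3(g)

    # -- per-layer projections to the common latent space ----------------
    def project_layers(self, feats: BlockFeatures) -> list[nn.Tensor]:
        target = feats.b3.shape[2:]
        out = []
        for lvl, tap in enumerate(feats.taps):
            x = tap
            while x.shape[2] > target[0] or x.shape[3] > target[1]:
                x = F.avg_pool2d(x, 2)
            if x.shape[2:] != target:
                x = F.resize_nearest(x, target)      # guard for odd geometries
            x = self.proj_bns[lvl](self.proj_convs[lvl](x)).relu()
            out.append(x)
        return out

    # -- reciprocal calibration ------------------------------------------
    def attend_patch(self, z_layers: list[nn.Tensor], h: nn.Tensor) -> nn.Tensor:
        """z_i = Concat over the three layer projections, each multiplied by
        the shared map h (tiled across the 512-channel groups).

        ``z_layers``: three (B*K, C, g, g); ``h``: (B, C, g, g)."""
        if len(z_layers) != len(self.proj_convs):
            raise ValueError(f"expected {len(self.proj_convs)} layer "
                             f"projections, got {len(z_layers)}")
        bk = z_layers[0].shape[0]
        b = h.shape[0]
        rep = np.repeat(np.arange(b), bk // b)
        h_rep = h[rep]                                # (B*K, C, g, g)
        return nn.concat([z * h_rep for z in z_layers], axis=1)


def reshape_to_image(z_patches: nn.Tensor, grid: tuple[int, int]) -> nn.Tensor:
    """Stitch per-patch features (B*K, C, g, g), row-major patch order, into
    the image-level map (B, C, n_rows*g, n_cols*g)."""
    n_cols, n_rows = grid
    k = n_cols * n_rows
    bk, c, gh, gw = z_patches.shape
    if bk % k:
        raise ValueError(f"feature count {bk} does not match grid {grid}")
    b = bk // k
    z = z_patches.reshape(b, n_rows, n_cols, c, gh, gw)
    z = z.transpose((0, 3, 1, 4, 2, 5))
    return z.reshape(b, c, n_rows * gh, n_cols * gw)
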