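"""The composite training objective.

    L = lambda_cls * L_cls + lambda_loc * (lambda_h * L_h + lambda_s * L_s)

with L_cls the 4-way cross entropy, L_h the mean squared error between the
predicted and target Gaussian heatmaps, and L_s the focal loss
-(1 - p_t)^gamma log p_t applied to the continuous heatmap interpreted as a
per-pixel lesion probability (thresholding is not differentiable).  All
weights default to 1.0; the focal exponent gamma defaults to 2.0.
Localization terms are masked to zero for Normal samples, so training is
unaffected by localization predictions on normal images.
"""

from __future__ import annotations

import numpy as np

from . import CLASSES, nn
from .config import LossWeights
from .nn import functional as F

__all__ = ["classification_loss", "heatmap_loss", "focal_segmentation_loss",
           "total_loss"]

_EPS = 1e-8


def _label_indices(labels) -> np.ndarray:
    if isinstance(labels[0], str):
        return np.array([CLASSES.index(t) for t in labels])
    return np.asarray(labels, int)


def classification_loss(scores, labels, from_logits: bool = False) -> nn.Tensor:
    """Batch-mean negative log probability of the true class.

    ``scores``: (N, 4) probabilities (or logits with ``from_logits=True``);
    ``labels``: class names or indices.  Zero probabilities are eps-clamped.
    """
    scores = nn.as_tensor(scores)
    idx = _label_indices(labels)
    n = scores.shape[0]
    onehot = np.zeros(scores.shape, np.float32)
    onehot[np.arange(n), idx] = 1.0
    if from_logits:
        logp = F.log_softmax(scores, axis=1)
    else:
        logp = (scores + _EPS).log()
    return -(logp * nn.Tensor(onehot)).sum() * (1.0 / n)


def heatmap_loss(pred, target) -> nn.Tensor:
    """Mean squared error over pixels and batch."""
    pred = nn.as_tensor(pred)
    target = nn.as_tensor(target)
    if pred.shape != target.shape:
        raise ValueError(f"heatmap shapes differ: {pred.shape} vs {target.shape}")
    return ((pred - target) ** 2.0).mean()


def focal_segmentation_loss(pred, target, gamma: float = 2.0) -> nn.Tensor:
    """Focal loss -(1-p_t)^gamma log(p_t) averaged over pixels and batch,
    with p_t = p where the binary target is 1 and 1-p elsewhere.  At
    gamma = 0 this reduces exactly to pixelwise binary cross entropy."""
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    pred = nn.as_tensor(pred)
    t = np.asarray(target.data if isinstance(target, nn.Tensor) else target,
                   np.float32)
    if pred.shape != t.shape:
        raise ValueError(f"segmentation shapes differ: {pred.shape} vs {t.shape}")
    tt = nn.Tensor(t)
    p_t = pred * tt + (1.0 - pred) * (1.0 - tt)
    logp = (p_t + _EPS).log()
    if gamma == 0.0:
        return -(logp.mean())
    return -(((1.0 - p_t) ** gamma * logp).mean())


def total_loss(logits, labels, pred_heatmap, target_heatmap,
               weights: LossWeights) -> tuple[nn.Tensor, dict]:
    """Composite objective plus per-component values for logging.

    ``pred_heatmap``/``target_heatmap``: (N, 1, h', w'); localization terms
    are computed per sample and masked to zero for Normal samples (mask then
    batch-mean, so an all-Normal batch contributes only L_cls).
    """
    weights.validate()
    l_cls = classification_loss(logits, labels, from_logits=True)

    idx = _label_indices(labels)
    abnormal = (idx != CLASSES.index("Normal")).astype(np.float32)
    n = len(abnormal)
    n_ab = float(abnormal.sum())
    if n_ab > 0:
        pred = nn.as_tensor(pred_heatmap)
        targ = nn.as_tensor(target_heatmap)
        mask = nn.Tensor(abnormal.reshape(n, 1, 1, 1))
        sq = ((pred - targ) ** 2.0).mean(axis=(1, 2, 3)).reshape(n, 1, 1, 1)
        l_h = (sq * mask).sum() * (1.0 / n)
        t = np.asarray(targ.data >= 0.5, np.float32)
        tt = nn.Tensor(t)
        p_t = pred * tt + (1.0 - pred) * (1.0 - tt)
        per_px = -(((1.0 - p_t) ** weights.focal_gamma) * (p_t + _EPS).log())
        l_s = (per_px.mean(axis=(1, 2, 3)).reshape(n, 1, 1, 1) * mask).sum() \
            * (1.0 / n)
    else:
        l_h = nn.Tensor(0.0)
        l_s = nn.Tensor(0.0)

    total = weights.lambda_cls * l_cls \
        + weights.lambda_loc * (weights.lambda_h * l_h + weights.lambda_s * l_s)
    components = {"cls": float(l_cls.data), "heatmap": float(l_h.data),
                  "focal": float(l_s.data), "total": float(total.data)}
    return total, components
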