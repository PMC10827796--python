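"""Two-step training protocol, splits and cross-validation.

Step 1 fine-tunes the dense backbone alone: random square crops (375x375 at
reference scale), drawn so lesion-overlapping windows appear three times
more often than lesion-free ones, are pushed through the encoder and a
throwaway decode head to predict the crop-level Gaussian heatmap under the
focal segmentation loss.

Step 2 trains everything else end-to-end under the composite loss with the
backbone parameters (and its normalization statistics) frozen — bitwise
unchanged after training.  Minibatches hold equal numbers of original and
LesionMix-synthesized samples, and online flip/rotation/intensity jitter is
applied on the fly.  Both steps use Adam with the per-epoch exponential
learning-rate schedule mu_t = mu_0 * decay^t.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import CLASSES, nn
from .augment import lesion_mix, online_augment
from .backbone import DenseEncoder
from .config import RunConfig, TrainSchedule
from .losses import focal_segmentation_loss, total_loss
from .model import TwoStageNet
from .nn import functional as F
from .nn.optim import Adam, exponential_lr
from .phantom import RadiographSample
from .preprocess import (crop_and_resize_sample, gaussian_heatmap_target,
                         preprocess_sample, sample_training_crop, standardize)

__all__ = ["lr_at", "finetune_backbone", "train_end_to_end", "make_splits",
           "save_history_csv"]


def save_history_csv(history: dict, path) -> None:
    """Write a per-epoch training log (loss components, lr, accuracy) as CSV."""
    import pandas as pd
    df = pd.DataFrame(history)
    df.index.name = "epoch"
    df.to_csv(path)


def lr_at(epoch: int, mu0: float, schedule: TrainSchedule) -> float:
    """Learning rate at epoch t: mu0 * decay^t."""
    return exponential_lr(mu0, schedule.decay, epoch)


class _CropSegHead(nn.Module):
    """Throwaway decode head for step 1: fuses the deepest tap into the
    stride-8 tap and upsamples to the crop-level target resolution."""

    def __init__(self, backbone: DenseEncoder, rng: np.random.Generator,
                 width: int = 16):
        super().__init__()
        c1 = backbone.tap_channels[0]
        c4 = backbone.out_channels
        self.fuse = nn.Conv2d(c1 + c4, width, 3, rng, padding=1)
        self.out = nn.Conv2d(width, 1, 1, rng, bias=True)

    def forward(self, feats, target_hw: tuple[int, int]) -> nn.Tensor:
        up = F.resize_nearest(feats.b4, feats.b1.shape[2:])
        x = self.fuse(nn.concat([feats.b1, up], axis=1)).relu()
        return F.resize_nearest(self.out(x), target_hw).sigmoid()


def finetune_backbone(samples: list[RadiographSample], cfg: RunConfig,
                      epochs: int | None = None,
                      rng: np.random.Generator | None = None
                      ) -> tuple[DenseEncoder, dict]:
    """Step 1.  Returns the fine-tuned backbone and a history dict with the
    per-epoch mean loss and learning rate."""
    cfg.validate()
    if not samples:
        raise ValueError("empty training set")
    sched = cfg.schedule
    rng = rng if rng is not None else np.random.default_rng(sched.seed)
    geo = cfg.geometry
    prepped = [preprocess_sample(s, geo) for s in samples]

    backbone = DenseEncoder(cfg.backbone, rng)
    head = _CropSegHead(backbone, rng)
    params = backbone.parameters() + head.parameters()
    opt = Adam(params, lr=sched.mu0_backbone)
    crop = geo.patch_size
    factor = geo.working_size[0] // geo.seg_size[0]
    target_hw = (crop // factor, crop // factor)
    n_epochs = sched.epochs if epochs is None else epochs
    batch = min(sched.batch_size, len(samples))

    history = {"loss": [], "lr": []}
    for epoch in range(n_epochs):
        opt.lr = lr_at(epoch, sched.mu0_backbone, sched)
        order = rng.permutation(len(prepped))
        losses = []
        for start in range(0, len(order), batch):
            idx = order[start:start + batch]
            crops, targets = [], []
            for i in idx:
                img, lesions = prepped[i]
                c, t, _ = sample_training_crop(img, lesions, crop, geo, rng)
                crops.append(c)
                targets.append(t)
            x = nn.Tensor(np.stack(crops)[:, None])
            t = np.stack(targets)[:, None]
            feats = backbone(x)
            pred = head(feats, target_hw)
            loss = focal_segmentation_loss(
                pred, (t >= geo.seg_threshold).astype(np.float32),
                cfg.loss.focal_gamma)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["loss"].append(float(np.mean(losses)))
        history["lr"].append(opt.lr)
    return backbone, history


def _make_batch(originals, donors, recipients, batch_size, lesionmix_params,
                rng, use_lesionmix: bool):
    """Half original, half LesionMix-synthesized samples."""
    n_orig = max(1, batch_size // 2) if use_lesionmix else batch_size
    chosen = list(originals[:n_orig])
    if use_lesionmix and donors and recipients:
        for _ in range(batch_size - len(chosen)):
            d = donors[int(rng.integers(0, len(donors)))]
            r = recipients[int(rng.integers(0, len(recipients)))]
            chosen.append(lesion_mix(d, r, lesionmix_params, rng))
    return chosen


def train_end_to_end(samples: list[RadiographSample], backbone: DenseEncoder,
                     cfg: RunConfig, epochs: int | None = None,
                     rng: np.random.Generator | None = None,
                     use_lesionmix: bool = True, use_online_aug: bool = True,
                     stop_when: tuple[float, float] | None = None
                     ) -> tuple[TwoStageNet, dict]:
    """Step 2: end-to-end training with the backbone frozen.

    ``stop_when = (accuracy, loss_reduction)`` optionally ends training once
    the train accuracy reaches the first value and the epoch loss has fallen
    by the given fraction from the first epoch.  Returns (model, history)
    with per-epoch loss components, learning rate and train accuracy.
    """
    cfg.validate()
    if not samples:
        raise ValueError("empty training set")
    sched = cfg.schedule
    rng = rng if rng is not None else np.random.default_rng(sched.seed)
    geo = cfg.geometry

    model = TwoStageNet(cfg, rng, backbone=backbone)
    model.freeze_backbone()
    params = [p for p in model.parameters() if p.requires_grad]
    opt = Adam(params, lr=sched.mu0_full)

    # geometric preprocessing (background crop + resize) happens once per
    # sample; augmentation then acts on the working-space image so the crop
    # geometry is stable across epochs
    work = [crop_and_resize_sample(s, geo) for s in samples]
    donors = [s for s in work if s.label != "Normal" and s.lesions]
    recipients = [s for s in work if s.label == "Normal"]
    if use_lesionmix and (not donors or not recipients):
        warnings.warn("LesionMix disabled: need both abnormal and Normal "
                      "samples", stacklevel=2)
        use_lesionmix = False

    # clean standardized tensors for train-accuracy evaluation
    eval_imgs = np.stack([standardize(s.image) for s in work])[:, None]
    eval_labels = [s.label for s in work]

    def train_accuracy() -> float:
        model.eval()
        with nn.no_grad():
            out = model(nn.Tensor(eval_imgs))
        pred = out.logits.data.argmax(axis=1)
        model.train()
        true = np.array([CLASSES.index(t) for t in eval_labels])
        return float(np.mean(pred == true))

    n_epochs = sched.epochs if epochs is None else epochs
    batch = min(sched.batch_size, 2 * len(samples))
    history = {"loss": [], "cls": [], "heatmap": [], "focal": [], "lr": [],
               "train_acc": []}
    model.train()
    for epoch in range(n_epochs):
        opt.lr = lr_at(epoch, sched.mu0_full, sched)
        order = rng.permutation(len(work))
        queue = [work[i] for i in order]
        comp_sums, n_steps = {"cls": 0.0, "heatmap": 0.0, "focal": 0.0,
                              "total": 0.0}, 0
        step_orig = max(1, batch // 2) if use_lesionmix else batch
        aug = cfg.online_aug
        for start in range(0, len(queue), step_orig):
            originals = queue[start:start + step_orig]
            batch_samples = _make_batch(originals, donors, recipients,
                                        len(originals) * 2 if use_lesionmix
                                        else len(originals),
                                        cfg.lesionmix, rng, use_lesionmix)
            imgs, labels, targets = [], [], []
            for s in batch_samples:
                s_aug = online_augment(
                    s, rng, p_flip=aug.p_flip, max_rotation=aug.max_rotation,
                    brightness=aug.brightness, contrast=aug.contrast,
                    saturation=aug.saturation, hue=aug.hue,
                ) if (use_online_aug and aug.enabled) else s
                imgs.append(standardize(s_aug.image))
                labels.append(s_aug.label)
                targets.append(gaussian_heatmap_target(s_aug.lesions, geo))
            x = nn.Tensor(np.stack(imgs)[:, None])
            t = np.stack(targets)[:, None]
            out = model(x)
            loss, comps = total_loss(out.logits, labels, out.heatmap, t, cfg.loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k in comp_sums:
                comp_sums[k] += comps[k]
            n_steps += 1
        for k in ("cls", "heatmap", "focal"):
            history[k].append(comp_sums[k] / n_steps)
        history["loss"].append(comp_sums["total"] / n_steps)
        history["lr"].append(opt.lr)
        acc = train_accuracy()
        history["train_acc"].append(acc)
        if stop_when is not None:
            acc_goal, red_goal = stop_when
            if (acc >= acc_goal and len(history["loss"]) > 1
                    and history["loss"][-1]
                    <= (1.0 - red_goal) * history["loss"][0]):
                break
    model.eval()
    return model, history


def make_splits(samples: list[RadiographSample], schedule: TrainSchedule
                ) -> list[dict]:
    """Stratified train/val/test splits (default 0.75/0.10/0.15) for
    ``schedule.folds`` folds with disjoint test partitions across folds.

    Returns a list of dicts of index lists.  Classes with fewer samples than
    folds degrade stratification with a warning.
    """
    schedule.validate()
    if not samples:
        raise ValueError("empty dataset")
    labels = [s.label for s in samples]
    classes = sorted(set(labels))
    rng = np.random.default_rng(schedule.seed)
    r_train, r_val, r_test = schedule.split_ratios
    perms = {}
    for cls in classes:
        idx = np.array([i for i, t in enumerate(labels) if t == cls])
        if len(idx) < schedule.folds:
            warnings.warn(f"class {cls} has {len(idx)} samples < "
                          f"{schedule.folds} folds: degraded stratification",
                          stacklevel=2)
        perms[cls] = idx[rng.permutation(len(idx))]

    folds = []
    for f in range(schedule.folds):
        train, val, test = [], [], []
        for cls in classes:
            perm = perms[cls]
            n = len(perm)
            lo = int(round(f * n * r_test))
            hi = int(round((f + 1) * n * r_test))
            test_c = perm[lo:hi]
            rest = np.concatenate([perm[:lo], perm[hi:]])
            n_val = int(round(n * r_val))
            val_c, train_c = rest[:n_val], rest[n_val:]
            train += train_c.tolist()
            val += val_c.tolist()
            test += test_c.tolist()
        folds.append({"train": sorted(train), "val": sorted(val),
                      "test": sorted(test)})
    return folds
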