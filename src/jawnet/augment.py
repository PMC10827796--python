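"""Data augmentation: LesionMix copy-paste synthesis, Mixup and CutMix
baselines, offline class balancing, and online geometric/photometric jitter.

LesionMix cuts a lesion out of an abnormal donor along its segmentation mask
and pastes it onto a normal recipient, producing a new labeled abnormal
sample.  The pixel-provenance contract is exact: outside the mask dilated by
``feather_radius`` the output equals the recipient bit-for-bit; inside the
mask eroded by ``feather_radius`` it equals the donor; in between, a monotone
distance-based blend.  By default the lesion is pasted at its donor
coordinates, preserving the positional prior the model is meant to learn.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .config import LesionMixParams
from .phantom import Lesion, RadiographSample, tight_bbox

__all__ = ["lesion_mix", "mixup", "cutmix", "balance_offline", "online_augment"]


def _feather_weights(mask: np.ndarray, radius: int) -> np.ndarray:
    """Blend weights: 1 strictly inside mask eroded by ``radius``, 0 strictly
    outside mask dilated by ``radius``, monotone (Euclidean distance ramp)
    in the feather band."""
    if radius == 0:
        return mask.astype(np.float32)
    # signed Euclidean distance to the mask boundary: >0 inside, <0 outside
    d_in = ndimage.distance_transform_edt(mask)
    d_out = ndimage.distance_transform_edt(~mask)
    signed = d_in - d_out
    return np.clip(0.5 + signed / (2.0 * radius), 0.0, 1.0).astype(np.float32)


def _shift_mask(mask: np.ndarray, dx: int, dy: int) -> np.ndarray:
    out = np.zeros_like(mask)
    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    ys2, xs2 = ys + dy, xs + dx
    if ys2.min() < 0 or xs2.min() < 0 or ys2.max() >= h or xs2.max() >= w:
        raise ValueError("shifted mask leaves the image bounds")
    out[ys2, xs2] = True
    return out


def lesion_mix(donor: RadiographSample, recipient: RadiographSample,
               params: LesionMixParams, rng: np.random.Generator
               ) -> RadiographSample:
    """Synthesize an abnormal sample from (abnormal donor, normal recipient)."""
    params.validate()
    if not donor.lesions or not any(l.mask.any() for l in donor.lesions):
        raise ValueError("donor must carry at least one non-empty lesion mask")
    if recipient.label != "Normal":
        raise ValueError("recipient must be a Normal sample")
    if donor.image.shape != recipient.image.shape:
        raise ValueError("donor and recipient must share the image size")

    union = np.zeros_like(donor.lesions[0].mask)
    for lesion in donor.lesions:
        union |= lesion.mask

    if params.placement == "donor_location":
        dx = dy = 0
        donor_img = donor.image
    else:  # random placement, keeping the mask inside bounds
        h, w = donor.image.shape
        x0, y0, x1, y1 = tight_bbox(union)
        for _ in range(params.max_attempts):
            dx = int(rng.integers(-x0, w - x1 + 1))
            dy = int(rng.integers(-y0, h - y1 + 1))
            try:
                _shift_mask(union, dx, dy)
                break
            except ValueError:
                continue
        else:
            raise ValueError(f"no in-bounds placement found in "
                             f"{params.max_attempts} attempts")
        donor_img = np.roll(np.roll(donor.image, dy, axis=0), dx, axis=1)

    placed = _shift_mask(union, dx, dy) if (dx or dy) else union
    w_blend = _feather_weights(placed, params.feather_radius)

    out = recipient.image.copy()
    active = w_blend > 0
    out[active] = (recipient.image[active] * (1.0 - w_blend[active])
                   + donor_img[active] * w_blend[active])
    # exactness inside the fully-donor region (avoid float blend residue)
    core = w_blend >= 1.0
    out[core] = donor_img[core]

    lesions = []
    for lesion in donor.lesions:
        m = _shift_mask(lesion.mask, dx, dy) if (dx or dy) else lesion.mask.copy()
        lesions.append(Lesion(mask=m, bbox=tight_bbox(m), cls=lesion.cls))
    return RadiographSample(
        image=out.astype(np.float32), label=donor.label, lesions=lesions,
        provenance="augmented",
        meta={"donor": donor.meta.get("id"), "recipient": recipient.meta.get("id"),
              "method": "lesionmix", "offset": (dx, dy)},
    ).validate()


def mixup(a, b, ratio: float) -> np.ndarray:
    """Elementwise convex blend ratio*a + (1-ratio)*b (baseline)."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("mixup ratio must lie in [0, 1]")
    ia = a.image if isinstance(a, RadiographSample) else np.asarray(a, np.float32)
    ib = b.image if isinstance(b, RadiographSample) else np.asarray(b, np.float32)
    if ia.shape != ib.shape:
        raise ValueError("mixup inputs must share a shape")
    if ratio == 1.0:
        return ia.copy()
    if ratio == 0.0:
        return ib.copy()
    return (np.float32(ratio) * ia + np.float32(1.0 - ratio) * ib).astype(np.float32)


def cutmix(a, b, rng: np.random.Generator,
           box: tuple[int, int, int, int] | None = None) -> np.ndarray:
    """Rectangular patch of ``a`` pasted into ``b`` (baseline).  A random box
    is drawn unless one is given; zero-area draws are resampled."""
    ia = a.image if isinstance(a, RadiographSample) else np.asarray(a, np.float32)
    ib = b.image if isinstance(b, RadiographSample) else np.asarray(b, np.float32)
    if ia.shape != ib.shape:
        raise ValueError("cutmix inputs must share a shape")
    h, w = ia.shape
    if box is None:
        for _ in range(100):
            lam = rng.uniform(0.0, 1.0)
            frac = np.sqrt(1.0 - lam)
            bw, bh = int(round(w * frac)), int(round(h * frac))
            if bw == 0 or bh == 0:
                continue
            cx, cy = int(rng.integers(0, w)), int(rng.integers(0, h))
            x0, y0 = np.clip(cx - bw // 2, 0, w - 1), np.clip(cy - bh // 2, 0, h - 1)
            x1, y1 = min(w, x0 + bw), min(h, y0 + bh)
            if x1 > x0 and y1 > y0:
                box = (int(x0), int(y0), int(x1), int(y1))
                break
        else:
            raise RuntimeError("failed to draw a non-degenerate cutmix box")
    x0, y0, x1, y1 = box
    out = ib.copy()
    out[y0:y1, x0:x1] = ia[y0:y1, x0:x1]
    return out


def balance_offline(samples: list[RadiographSample], target_counts: dict,
                    rng: np.random.Generator) -> list[RadiographSample]:
    """Offline oversampling to the requested per-class counts (e.g.
    75/97/193/200 -> 200/194/193/200).  Added samples are flagged duplicates
    and the result is deterministic under the given generator."""
    by_class: dict[str, list[RadiographSample]] = {}
    for s in samples:
        by_class.setdefault(s.label, []).append(s)
    out = list(samples)
    for cls in sorted(target_counts):
        have = len(by_class.get(cls, []))
        want = target_counts[cls]
        if want < have:
            raise ValueError(f"target for {cls} ({want}) below current count ({have})")
        if want == have:
            continue
        if have == 0:
            raise ValueError(f"cannot oversample class {cls}: no source samples")
        pool = by_class[cls]
        order = rng.permutation(have)
        for k in range(want - have):
            src = pool[order[k % have]]
            dup = RadiographSample(
                image=src.image.copy(), label=src.label,
                lesions=[Lesion(l.mask.copy(), l.bbox, l.cls) for l in src.lesions],
                provenance=src.provenance,
                meta={**src.meta, "duplicate": True,
                      "duplicate_of": src.meta.get("id")})
            out.append(dup)
    return out


def online_augment(sample: RadiographSample, rng: np.random.Generator,
                   p_flip: float = 0.5, max_rotation: float = 5.0,
                   brightness: float = 1.0, contrast: float = 1.0,
                   saturation: float = 1.0, hue: float = 0.5
                   ) -> RadiographSample:
    """Random flips (p=0.5 each), rotation up to +/-5 degrees, and intensity
    jitter; masks and boxes are transformed consistently.

    Saturation and hue jitter have no effect on single-channel images and are
    carried as no-ops (a single warning is raised on first use); brightness
    and contrast act as grayscale intensity transforms with torch-style
    factor ranges [max(0, 1-s), 1+s].
    """
    img = sample.image
    masks = [l.mask for l in sample.lesions]

    # fixed draw order so the consumed random stream is parameter-independent
    do_h = rng.random() < p_flip
    do_v = rng.random() < p_flip
    angle = float(rng.uniform(-max_rotation, max_rotation))
    f_b = float(rng.uniform(max(0.0, 1.0 - brightness), 1.0 + brightness))
    f_c = float(rng.uniform(max(0.0, 1.0 - contrast), 1.0 + contrast))
    _ = rng.uniform(max(0.0, 1.0 - saturation), 1.0 + saturation)  # no-op, 1ch
    _ = rng.uniform(-hue, hue)                                     # no-op, 1ch
    if (saturation > 0 or hue > 0) and not getattr(online_augment, "_warned", False):
        warnings.warn("saturation/hue jitter is a no-op on single-channel images",
                      stacklevel=2)
        online_augment._warned = True

    if do_h:
        img = img[:, ::-1]
        masks = [m[:, ::-1] for m in masks]
    if do_v:
        img = img[::-1, :]
        masks = [m[::-1, :] for m in masks]
    if angle != 0.0:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        masks = [ndimage.rotate(m.astype(np.uint8), angle, reshape=False,
                                order=0, mode="constant") > 0 for m in masks]
    if f_b != 1.0:
        img = img * f_b
    if f_c != 1.0:
        mu = img.mean()
        img = mu + (img - mu) * f_c
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    lesions = []
    for m, src in zip(masks, sample.lesions):
        if not m.any():
            warnings.warn("lesion mask emptied by augmentation; dropped", stacklevel=2)
            continue
        lesions.append(Lesion(mask=np.ascontiguousarray(m),
                              bbox=tight_bbox(m), cls=src.cls))
    label = sample.label if lesions or sample.label == "Normal" else "Normal"
    return RadiographSample(image=np.ascontiguousarray(img), label=label,
                            lesions=lesions, provenance="augmented",
                            meta={**sample.meta, "online_aug": True}).validate()
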