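"""Preprocessing: background cropping, standardization, patch tiling,
Gaussian heatmap targets, and lesion-biased training-crop sampling.

The working geometry is fixed by the configuration: the preprocessed image is
resized to ``working_size`` (reference 1500x750), tiled into a row-major grid
of non-overlapping square patches (reference 4x2 of 375x375), and localization
targets live at ``seg_size`` (reference 750x375), half the working resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .config import GeometryConfig
from .phantom import Lesion, RadiographSample, tight_bbox

__all__ = [
    "PatchGrid",
    "preprocess_image",
    "preprocess_sample",
    "crop_and_resize_sample",
    "standardize",
    "split_into_patches",
    "stitch_patches",
    "gaussian_heatmap_target",
    "sample_training_crop",
]

_EPS = 1e-8


def _content_box(raw: np.ndarray, pad_frac: float = 0.01) -> tuple[int, int, int, int]:
    """Otsu-threshold bounding box of the bright content, padded by 1%."""
    h, w = raw.shape
    if float(raw.max() - raw.min()) < 1e-6:
        return 0, 0, w, h
    th = threshold_otsu(raw)
    mask = raw > th
    if not mask.any():
        return 0, 0, w, h
    x0, y0, x1, y1 = tight_bbox(mask)
    px, py = int(round(pad_frac * w)), int(round(pad_frac * h))
    return max(0, x0 - px), max(0, y0 - py), min(w, x1 + px), min(h, y1 + py)


def standardize(img: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-std per image, with a guard for constant images."""
    img = np.asarray(img, np.float32)
    mu = float(img.mean())
    sd = float(img.std())
    if sd < _EPS:
        warnings.warn("constant image: standardized to all zeros", stacklevel=2)
    return ((img - mu) / max(sd, _EPS)).astype(np.float32)


def preprocess_image(raw: np.ndarray, cfg: GeometryConfig,
                     return_box: bool = False):
    """Crop the dark border around the jaws, resize to the working
    resolution, and standardize to mean 0 / std 1."""
    raw = np.asarray(raw, np.float32)
    if raw.size == 0:
        raise ValueError("empty image")
    x0, y0, x1, y1 = _content_box(raw)
    cropped = raw[y0:y1, x0:x1]
    w, h = cfg.working_size
    resized = resize(cropped, (h, w), order=1, anti_aliasing=True,
                     preserve_range=True).astype(np.float32)
    out = standardize(resized)
    if return_box:
        return out, (x0, y0, x1, y1)
    return out


def crop_and_resize_sample(sample: RadiographSample, cfg: GeometryConfig
                           ) -> RadiographSample:
    """Geometric preprocessing only: background crop + resize to the working
    resolution, masks carried along (nearest-neighbour), intensities kept in
    [0, 1].  Standardization is applied separately so that photometric
    augmentation can act on the un-standardized working image."""
    x0, y0, x1, y1 = _content_box(sample.image)
    w, h = cfg.working_size
    img = resize(sample.image[y0:y1, x0:x1], (h, w), order=1,
                 anti_aliasing=True, preserve_range=True).astype(np.float32)
    img = np.clip(img, 0.0, 1.0)
    lesions = []
    for lesion in sample.lesions:
        m = lesion.mask[y0:y1, x0:x1]
        m = resize(m.astype(np.float32), (h, w), order=0,
                   preserve_range=True) > 0.5
        if not m.any():
            warnings.warn("lesion lost in preprocessing crop/resize", stacklevel=2)
            continue
        lesions.append(Lesion(mask=m, bbox=tight_bbox(m), cls=lesion.cls))
    label = sample.label if (lesions or sample.label == "Normal") else "Normal"
    return RadiographSample(image=img, label=label, lesions=lesions,
                            provenance=sample.provenance,
                            meta=dict(sample.meta))


def preprocess_sample(sample: RadiographSample, cfg: GeometryConfig
                      ) -> tuple[np.ndarray, list[Lesion]]:
    """Full preprocessing into working coordinates: crop, resize, masks
    carried along, image standardized to mean 0 / std 1."""
    work = crop_and_resize_sample(sample, cfg)
    return standardize(work.image), work.lesions


# ----------------------------------------------------------------------
# patch tiling


@dataclass
class PatchGrid:
    """Row-major tiling of the working image into K = n_cols * n_rows
    non-overlapping square patches. ``index_map[i]`` = (col, row, x0, y0)."""

    patches: list
    grid: tuple[int, int]          # (n_cols, n_rows)
    patch_size: int

    @property
    def index_map(self) -> list[tuple[int, int, int, int]]:
        n_cols, n_rows = self.grid
        p = self.patch_size
        return [(i % n_cols, i // n_cols, (i % n_cols) * p, (i // n_cols) * p)
                for i in range(n_cols * n_rows)]

    def __len__(self) -> int:
        return len(self.patches)


def split_into_patches(image: np.ndarray, cfg: GeometryConfig) -> PatchGrid:
    h, w = image.shape
    if (w, h) != tuple(cfg.working_size):
        raise ValueError(f"image size {(w, h)} != working size {cfg.working_size}")
    n_cols, n_rows = cfg.grid
    p = cfg.patch_size
    patches = [image[r * p:(r + 1) * p, c * p:(c + 1) * p]
               for r in range(n_rows) for c in range(n_cols)]
    return PatchGrid(patches=patches, grid=cfg.grid, patch_size=p)


def stitch_patches(grid: PatchGrid) -> np.ndarray:
    n_cols, n_rows = grid.grid
    p = grid.patch_size
    out = np.empty((n_rows * p, n_cols * p), dtype=grid.patches[0].dtype)
    for i, patch in enumerate(grid.patches):
        r, c = divmod(i, n_cols)
        out[r * p:(r + 1) * p, c * p:(c + 1) * p] = patch
    return out


# ----------------------------------------------------------------------
# heatmap targets


def gaussian_heatmap_target(lesions: list[Lesion], cfg: GeometryConfig) -> np.ndarray:
    """Per-lesion isotropic Gaussian (peak 1 at the bbox centre, variance
    ``cfg.heatmap_variance`` in seg-map pixels^2), combined across lesions by
    pointwise maximum, at ``seg_size`` resolution.  Normal -> all zeros."""
    sw, sh = cfg.seg_size
    scale = sw / cfg.working_size[0]
    target = np.zeros((sh, sw), np.float32)
    if not lesions:
        return target
    yy, xx = np.mgrid[0:sh, 0:sw].astype(np.float32)
    var = cfg.heatmap_variance
    for lesion in lesions:
        cx, cy = lesion.center
        cxs = int(round(cx * scale))
        cys = int(round(cy * scale))
        if not (0 <= cxs < sw and 0 <= cys < sh):
            raise ValueError(f"lesion centre {(cxs, cys)} outside the seg map "
                             f"{cfg.seg_size} — annotation bug")
        d2 = (xx - cxs) ** 2 + (yy - cys) ** 2
        np.maximum(target, np.exp(-d2 / (2.0 * var)), out=target)
    return target


# ----------------------------------------------------------------------
# lesion-biased crop sampling (backbone fine-tuning)


def _window_overlaps(x0: int, y0: int, size: int, bbox) -> bool:
    bx0, by0, bx1, by1 = bbox
    return x0 < bx1 and x0 + size > bx0 and y0 < by1 and y0 + size > by0


def sample_training_crop(image: np.ndarray, lesions: list[Lesion],
                         crop_size: int, cfg: GeometryConfig,
                         rng: np.random.Generator,
                         overlap_prob: float = 0.75
                         ) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Random square crop plus the matching window of the full heatmap target.

    Crops overlapping a lesion bounding box are drawn ``overlap_prob`` of the
    time (3:1 by default, i.e. lesion-overlapping windows three times more
    often than lesion-free ones); samples without lesions are cropped
    uniformly.  Origins are snapped to the working->seg integer factor so the
    target window aligns exactly.

    Returns (crop, crop_target, (x0, y0)).
    """
    h, w = image.shape
    if crop_size > min(h, w):
        raise ValueError("crop_size exceeds image size")
    factor = cfg.working_size[0] // cfg.seg_size[0]
    max_x = (w - crop_size) // factor
    max_y = (h - crop_size) // factor

    def uniform_origin():
        return (int(rng.integers(0, max_x + 1)) * factor,
                int(rng.integers(0, max_y + 1)) * factor)

    if not lesions:
        x0, y0 = uniform_origin()
    elif rng.random() < overlap_prob:
        lesion = lesions[int(rng.integers(0, len(lesions)))]
        bx0, by0, bx1, by1 = lesion.bbox
        lo_x = max(0, (bx0 - crop_size + 1 + factor - 1) // factor)
        hi_x = min(max_x, (bx1 - 1) // factor)
        lo_y = max(0, (by0 - crop_size + 1 + factor - 1) // factor)
        hi_y = min(max_y, (by1 - 1) // factor)
        x0 = int(rng.integers(lo_x, hi_x + 1)) * factor
        y0 = int(rng.integers(lo_y, hi_y + 1)) * factor
    else:
        for _ in range(200):
            x0, y0 = uniform_origin()
            if not any(_window_overlaps(x0, y0, crop_size, l.bbox) for l in lesions):
                break
        else:
            warnings.warn("could not find a lesion-free crop; using overlap",
                          stacklevel=2)

    full_target = gaussian_heatmap_target(lesions, cfg)
    ct = crop_size // factor
    target = full_target[y0 // factor: y0 // factor + ct,
                         x0 // factor: x0 // factor + ct]
    crop = image[y0:y0 + crop_size, x0:x0 + crop_size]
    return crop, target, (x0, y0)
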