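"""Synthetic panoramic-radiograph phantoms.

The real clinical corpus behind this architecture (565 radiographs, 3000x1500,
with 75 ameloblastoma / 97 odontogenic keratocyst / 193 dentigerous cyst / 200
normal cases) is private, so this module generates stand-in images that copy
its *statistical* structure: the class counts, a log-uniform lesion-size
spread, a strong positional bias toward the posterior (lower) jaw, and a
near-black border around the jaws.  The images are coarse phantoms — a bright
jaw arch with tooth-like ripples on a dark background — not anatomically
convincing radiographs.

Class-conditional lesion texture is deterministic so a classifier can in
principle separate the classes:

* ``AB``  — multilocular "soap-bubble" interior: strong high-frequency septa.
* ``OKC`` — multilocular with milder, coarser internal structure.
* ``DC``  — unilocular: smooth radiolucent interior with a bright corticated
  rim.

Every sample is a pure function of (spec, seed): the same spec and seed give
byte-identical pixel arrays.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import CLASSES, LESION_CLASSES
from .evaluation import quadrant_of

__all__ = [
    "Lesion",
    "RadiographSample",
    "PhantomSpec",
    "PhantomDataset",
    "tight_bbox",
    "generate_sample",
    "generate_dataset",
    "paper_scale_spec",
    "tiny_spec",
]


def tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight half-open bounding box (x0, y0, x1, y1) of a binary mask."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask has no bounding box")
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


@dataclass
class Lesion:
    mask: np.ndarray                      # bool (H, W)
    bbox: tuple[int, int, int, int]       # half-open, x rightward, y downward
    cls: str

    def validate(self, image_shape: tuple[int, int]) -> None:
        if self.mask.shape != image_shape:
            raise ValueError("lesion mask shape differs from image shape")
        if self.cls not in LESION_CLASSES:
            raise ValueError(f"unknown lesion class {self.cls!r}")
        if tuple(self.bbox) != tight_bbox(self.mask):
            raise ValueError("bbox is not the tight box of the mask")

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.bbox
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class RadiographSample:
    image: np.ndarray                     # float32 (H, W) in [0, 1]
    label: str
    lesions: list[Lesion] = field(default_factory=list)
    provenance: str = "synthetic"         # real | synthetic | augmented
    meta: dict = field(default_factory=dict)

    def validate(self) -> "RadiographSample":
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")
        if (self.label == "Normal") != (len(self.lesions) == 0):
            raise ValueError("label is Normal iff the lesion list is empty")
        for lesion in self.lesions:
            lesion.validate(self.image.shape)
        return self

    @property
    def size(self) -> tuple[int, int]:
        """(width, height)."""
        h, w = self.image.shape
        return (w, h)


@dataclass
class PhantomSpec:
    image_width: int = 3000
    image_height: int = 1500
    class_counts: dict = field(default_factory=lambda: {
        "AB": 75, "OKC": 97, "DC": 193, "Normal": 200})
    lesion_size_range: tuple[float, float] = (2500.0, 180000.0)   # px^2
    positional_bias: dict = field(default_factory=lambda: {
        1: 0.1, 2: 0.1, 3: 0.4, 4: 0.4})   # quadrants, 1=upper-right CCW
    background_margin: float = 0.04         # border fraction left near-black
    max_lesions: int = 1                    # >1 enables multi-lesion phantoms
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be nonnegative")
        if set(self.class_counts) - set(CLASSES):
            raise ValueError("class_counts keys must be in " + str(CLASSES))
        probs = np.array([self.positional_bias.get(q, 0.0) for q in (1, 2, 3, 4)])
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("positional_bias must be a probability map over quadrants 1-4")
        lo, hi = self.lesion_size_range
        if lo <= 0 or lo > hi:
            raise ValueError("lesion size range must be positive with min <= max")
        # the largest lesion (with boundary modulation and margins) must fit a quadrant
        if 2.2 * np.sqrt(hi / np.pi) + self.margin_px >= min(self.image_width,
                                                             self.image_height) / 2:
            raise ValueError(
                "lesion_size_range incompatible with image dimensions: the largest "
                "lesion cannot fit inside one quadrant with the background margin")
        if not 0 <= self.background_margin < 0.5:
            raise ValueError("background_margin must lie in [0, 0.5)")
        if self.max_lesions < 1:
            raise ValueError("max_lesions must be >= 1")
        return self

    @property
    def margin_px(self) -> int:
        return int(round(self.background_margin * min(self.image_width, self.image_height)))

    def hash(self) -> str:
        payload = {k: (sorted(v.items()) if isinstance(v, dict) else v)
                   for k, v in self.__dict__.items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def paper_scale_spec(seed: int = 0) -> PhantomSpec:
    """Full-scale spec mirroring the clinical corpus statistics."""
    return PhantomSpec(seed=seed).validate()


def tiny_spec(seed: int = 0, counts: dict | None = None) -> PhantomSpec:
    """300x150 desk-scale spec used throughout the test suite.

    The lesion-area range applies the profile's geometric scaling rule —
    areas shrink by (1/5)^2 relative to the full-scale range, like the
    heatmap variance — truncated above at the largest lesion a 300x150
    quadrant can host with the background margin."""
    return PhantomSpec(
        image_width=300, image_height=150,
        class_counts=counts or {"AB": 2, "OKC": 2, "DC": 2, "Normal": 2},
        lesion_size_range=(100.0, 3000.0),
        seed=seed,
    ).validate()


# ----------------------------------------------------------------------
# image synthesis


def _jaw_background(w: int, h: int, margin: int, rng: np.random.Generator) -> np.ndarray:
    """Dark field + bright parabolic mandible/maxilla arches + tooth ripples."""
    y, x = np.mgrid[0:h, 0:w].astype(np.float32)
    u = 2.0 * x / w - 1.0                       # -1 .. 1 across the width
    img = 0.04 + 0.02 * rng.standard_normal((h, w)).astype(np.float32)

    # mandible: U-shaped band in the lower half
    yc_lo = h * (0.60 + 0.16 * u * u)
    img += 0.42 * np.exp(-((y - yc_lo) ** 2) / (2 * (0.075 * h) ** 2))
    # maxilla: inverted arch in the upper half
    yc_hi = h * (0.42 - 0.08 * u * u)
    img += 0.30 * np.exp(-((y - yc_hi) ** 2) / (2 * (0.055 * h) ** 2))
    # tooth-like ripples between the arches
    occlusal = np.exp(-((y - h * 0.5) ** 2) / (2 * (0.08 * h) ** 2))
    img += 0.18 * occlusal * np.maximum(0.0, np.sin(x * (28 * np.pi / w))) ** 2

    if margin > 0:
        edge = np.ones((h, w), np.float32)
        ramp = np.minimum(1.0, np.minimum.reduce(
            [x / margin, (w - 1 - x) / margin, y / margin, (h - 1 - y) / margin]))
        edge *= np.clip(ramp, 0.02, 1.0)
        img *= edge
    return np.clip(img, 0.0, 1.0)


def _lesion_mask(w: int, h: int, cx: float, cy: float, area: float, cls: str,
                 rng: np.random.Generator) -> np.ndarray:
    """Blobby ellipse of roughly ``area`` px^2 centred at (cx, cy)."""
    r0 = np.sqrt(area / np.pi)
    aspect = rng.uniform(0.75, 1.35)
    a, b = r0 * np.sqrt(aspect), r0 / np.sqrt(aspect)
    theta = rng.uniform(0.0, np.pi)
    # scalloped boundary for the multilocular classes, smoother for DC
    amp = {"AB": 0.18, "OKC": 0.22, "DC": 0.07}[cls]
    harmonics = rng.integers(2, 6, size=2)
    phases = rng.uniform(0, 2 * np.pi, size=2)
    amps = amp * rng.uniform(0.5, 1.0, size=2)

    y, x = np.mgrid[0:h, 0:w].astype(np.float32)
    dx, dy = x - cx, y - cy
    ct, st = np.cos(theta), np.sin(theta)
    xr = dx * ct + dy * st
    yr = -dx * st + dy * ct
    r_ell = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    phi = np.arctan2(yr, xr)
    boundary = 1.0 + sum(am * np.sin(k * phi + p)
                         for am, k, p in zip(amps, harmonics, phases))
    return r_ell <= boundary


def _lesion_texture(img: np.ndarray, mask: np.ndarray, cls: str, cx: float, cy: float,
                    r0: float, rng: np.random.Generator) -> None:
    """Write class-specific radiolucent texture into ``img`` (in place)."""
    h, w = img.shape
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    sub = img[y0:y1, x0:x1]
    m = mask[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float32)
    dx, dy = xx - cx, yy - cy
    rr = np.sqrt(dx * dx + dy * dy) / max(r0, 1.0)

    base = sub * 0.30 + 0.06                      # radiolucent interior
    # septa wavelengths keep a floor well above the resampling (rotation /
    # resize) blur radius so class texture survives online augmentation
    if cls == "AB":                               # dense soap-bubble septa
        lam = max(5.0, r0 / 2.2)
        sept = (np.sin(2 * np.pi * dx / lam + rng.uniform(0, 2 * np.pi))
                * np.sin(2 * np.pi * dy / lam + rng.uniform(0, 2 * np.pi)))
        base = base + 0.50 * sept ** 2
    elif cls == "OKC":                            # coarser, milder loculation
        lam = max(10.0, r0 / 1.1)
        sept = np.sin(2 * np.pi * dx / lam + rng.uniform(0, 2 * np.pi)) \
            * np.sin(2 * np.pi * dy / lam + rng.uniform(0, 2 * np.pi))
        base = base + 0.30 * sept ** 2
    else:                                         # DC: smooth with bright rim
        base = base + 0.02 * np.cos(rng.uniform(0, 2 * np.pi) + 2 * np.pi * rr)
        base = base + 0.35 * np.exp(-((rr - 1.0) ** 2) / (2 * 0.05 ** 2))
    sub[m] = np.clip(base, 0.0, 1.0)[m]


def _sample_center(spec: PhantomSpec, rmax: float, rng: np.random.Generator
                   ) -> tuple[float, float]:
    w, h = spec.image_width, spec.image_height
    cx0, cy0 = w / 2.0, h / 2.0
    pad = rmax + spec.margin_px + 2
    q = int(rng.choice([1, 2, 3, 4],
                       p=[spec.positional_bias.get(i, 0.0) for i in (1, 2, 3, 4)]))
    xlo, xhi = (cx0, w - pad) if q in (1, 4) else (pad, cx0)
    ylo, yhi = (pad, cy0) if q in (1, 2) else (cy0, h - pad)
    xlo, xhi = max(xlo, pad), min(xhi, w - pad)
    ylo, yhi = max(ylo, pad), min(yhi, h - pad)
    if xhi <= xlo or yhi <= ylo:
        raise ValueError("lesion size range incompatible with image dimensions "
                         f"(no room for radius {rmax:.0f} in quadrant {q})")
    cx, cy = rng.uniform(xlo, xhi), rng.uniform(ylo, yhi)
    # keep the draw honest: the centre must actually lie in the drawn quadrant
    if quadrant_of(cx, cy, cx0, cy0) != q:   # boundary rounding
        cx = np.nextafter(cx, cx0 + (1 if q in (1, 4) else -1) * w)
    return cx, cy


def generate_sample(spec: PhantomSpec, lesion_class: str,
                    rng: np.random.Generator) -> RadiographSample:
    """One phantom radiograph; ``lesion_class`` in {AB, OKC, DC, Normal}."""
    spec.validate()
    if lesion_class not in CLASSES:
        raise ValueError(f"unknown class {lesion_class!r}")
    w, h = spec.image_width, spec.image_height
    img = _jaw_background(w, h, spec.margin_px, rng)

    lesions: list[Lesion] = []
    if lesion_class != "Normal":
        n = 1 if spec.max_lesions == 1 else int(rng.integers(1, spec.max_lesions + 1))
        for _ in range(n):
            lo, hi = spec.lesion_size_range
            area = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            r0 = np.sqrt(area / np.pi)
            rmax = 1.55 * r0                      # aspect + boundary modulation bound
            cx, cy = _sample_center(spec, rmax, rng)
            mask = _lesion_mask(w, h, cx, cy, area, lesion_class, rng)
            if not mask.any():
                continue
            _lesion_texture(img, mask, lesion_class, cx, cy, r0, rng)
            lesions.append(Lesion(mask=mask, bbox=tight_bbox(mask), cls=lesion_class))
        if not lesions:
            raise RuntimeError("failed to draw a lesion (degenerate spec)")

    return RadiographSample(image=img.astype(np.float32), label=lesion_class,
                            lesions=lesions, provenance="synthetic").validate()


class PhantomDataset(list):
    """List of samples plus a provenance manifest (seed + spec hash)."""

    def __init__(self, samples, manifest: dict):
        super().__init__(samples)
        self.manifest = manifest


def generate_dataset(spec: PhantomSpec) -> PhantomDataset:
    """All samples of ``spec.class_counts``, deterministically shuffled."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    samples: list[RadiographSample] = []
    total = sum(spec.class_counts.values())
    if total == 0:
        import warnings
        warnings.warn("class_counts sum to zero: empty dataset", stacklevel=2)
    for cls in CLASSES:                            # fixed class order for determinism
        for i in range(spec.class_counts.get(cls, 0)):
            s = generate_sample(spec, cls, rng)
            s.meta["id"] = f"{cls}_{i:04d}"
            samples.append(s)
    order = rng.permutation(len(samples))
    manifest = {"seed": spec.seed, "spec_hash": spec.hash(), "n_samples": len(samples),
                "class_counts": dict(spec.class_counts)}
    return PhantomDataset([samples[i] for i in order], manifest)
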