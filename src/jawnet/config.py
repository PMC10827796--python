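"""Configuration objects and the two standard profiles.

The ``reference`` profile reproduces every printed dimension of the published
architecture: 1500x750 working resolution tiled into a 4x2 grid of 375x375
patches, feature taps of 47/23/11 cells, a 512-channel global attention map,
a 1536x44x22 stitched image-level map, a 750x375 localization output,
top-400 proposal merging, heatmap variance 50 px^2 and segmentation
threshold 0.5.

The ``tiny`` profile scales geometry by 1/5 and channel widths by 1/8 so the
whole two-stage pipeline trains on a laptop CPU in minutes; every shape
relation of the reference profile is preserved (the test suite checks the
shape algebra on both).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class GeometryConfig:
    raw_size: tuple[int, int] = (3000, 1500)        # (w, h) of incoming images
    working_size: tuple[int, int] = (1500, 750)     # (w, h) after preprocessing
    grid: tuple[int, int] = (4, 2)                  # (n_cols, n_rows)
    patch_size: int = 375
    seg_size: tuple[int, int] = (750, 375)          # (w', h') of the heatmap output
    heatmap_variance: float = 50.0                  # sigma^2, in seg-map pixel^2
    seg_threshold: float = 0.5                      # th_s

    @property
    def n_patches(self) -> int:
        return self.grid[0] * self.grid[1]

    def validate(self) -> "GeometryConfig":
        w, h = self.working_size
        if w != self.grid[0] * self.patch_size or h != self.grid[1] * self.patch_size:
            raise ValueError("working_size must equal grid * patch_size")
        sw, sh = self.seg_size
        if w % sw or h % sh or w // sw != h // sh:
            raise ValueError("seg_size must divide working_size by one integer factor")
        if not 0.0 <= self.seg_threshold <= 1.0:
            raise ValueError("seg_threshold must lie in [0, 1]")
        if self.heatmap_variance <= 0:
            raise ValueError("heatmap_variance must be positive")
        return self


@dataclass
class BackboneConfig:
    block_layer_counts: tuple[int, int, int, int] = (6, 12, 24, 16)
    growth_rate: int = 32
    init_channels: int = 64
    width_scale: float = 1.0
    in_channels: int = 1

    @property
    def growth(self) -> int:
        return max(1, round(self.growth_rate * self.width_scale))

    @property
    def stem_channels(self) -> int:
        return max(2, round(self.init_channels * self.width_scale))

    def validate(self) -> "BackboneConfig":
        if len(self.block_layer_counts) != 4 or min(self.block_layer_counts) < 1:
            raise ValueError("block_layer_counts must be 4 positive integers")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")
        return self


@dataclass
class ModelConfig:
    attn_channels: int = 512          # h_i / global map channels
    fpn_channels: int = 256           # lateral/pyramid width of the proposal FPN
    n_lesion_classes: int = 3
    top_k: int = 400                  # proposals merged into the local heatmap
    zreduce_channels: int = 64        # 1x1-reduced z_x fed to the decoder
    mlp_hidden: tuple[int, int] = (256, 256)
    loc_channels: tuple[int, int, int, int] = (16, 32, 64, 128)

    def validate(self) -> "ModelConfig":
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        return self


@dataclass
class LossWeights:
    lambda_cls: float = 1.0
    lambda_loc: float = 1.0
    lambda_h: float = 1.0
    lambda_s: float = 1.0
    focal_gamma: float = 2.0

    def validate(self) -> "LossWeights":
        for name in ("lambda_cls", "lambda_loc", "lambda_h", "lambda_s", "focal_gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        return self


@dataclass
class TrainSchedule:
    decay: float = 0.98               # per-epoch exponential LR multiplier
    mu0_backbone: float = 1e-4
    mu0_full: float = 5e-4
    epochs: int = 200
    batch_size: int = 48
    split_ratios: tuple[float, float, float] = (0.75, 0.10, 0.15)
    folds: int = 5
    seed: int = 0

    def validate(self) -> "TrainSchedule":
        if not 0 < self.decay <= 1:
            raise ValueError("decay must lie in (0, 1]")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        return self


@dataclass
class LesionMixParams:
    feather_radius: int = 2
    placement: str = "donor_location"   # or "random_in_bias_region"
    max_attempts: int = 20

    def validate(self) -> "LesionMixParams":
        if self.feather_radius < 0:
            raise ValueError("feather_radius must be >= 0")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        if self.placement not in ("donor_location", "random_in_bias_region"):
            raise ValueError(f"unknown placement {self.placement!r}")
        return self


@dataclass
class OnlineAugmentParams:
    """Online augmentation strengths.  Flip probability and rotation range
    follow the published protocol at every scale; the intensity-jitter
    strengths are a per-profile choice (strength 1.0 on clipped
    single-channel images lets the brightness factor reach 0, i.e. an
    all-black image, which is degenerate for narrow desk-scale models)."""
    enabled: bool = True
    p_flip: float = 0.5
    max_rotation: float = 5.0
    brightness: float = 1.0
    contrast: float = 1.0
    saturation: float = 1.0
    hue: float = 0.5

    def validate(self) -> "OnlineAugmentParams":
        if not 0.0 <= self.p_flip <= 1.0:
            raise ValueError("p_flip must lie in [0, 1]")
        if self.max_rotation < 0:
            raise ValueError("max_rotation must be nonnegative")
        return self


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossWeights = field(default_factory=LossWeights)
    schedule: TrainSchedule = field(default_factory=TrainSchedule)
    lesionmix: LesionMixParams = field(default_factory=LesionMixParams)
    online_aug: OnlineAugmentParams = field(default_factory=OnlineAugmentParams)
    profile: str = "reference"
    seed: int = 0

    def validate(self) -> "RunConfig":
        for sub in (self.geometry, self.backbone, self.model, self.loss,
                    self.schedule, self.lesionmix, self.online_aug):
            sub.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def _tup(d):
            return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}

        return cls(
            geometry=GeometryConfig(**_tup(raw.get("geometry", {}))),
            backbone=BackboneConfig(**_tup(raw.get("backbone", {}))),
            model=ModelConfig(**_tup(raw.get("model", {}))),
            loss=LossWeights(**raw.get("loss", {})),
            schedule=TrainSchedule(**_tup(raw.get("schedule", {}))),
            lesionmix=LesionMixParams(**raw.get("lesionmix", {})),
            online_aug=OnlineAugmentParams(**raw.get("online_aug", {})),
            profile=raw.get("profile", "reference"),
            seed=raw.get("seed", 0),
        ).validate()


def reference_config(seed: int = 0) -> RunConfig:
    """The full-scale published architecture."""
    return RunConfig(profile="reference", seed=seed).validate()


def tiny_config(seed: int = 0) -> RunConfig:
    """Desk-scale profile: geometry / 5, widths / 8, same shape algebra.

    The heatmap variance scales with length squared (50 / 5^2 = 2 px^2) so the
    Gaussian footprint keeps the same proportion of the image.
    """
    return RunConfig(
        geometry=GeometryConfig(
            raw_size=(300, 150), working_size=(300, 150), grid=(4, 2),
            patch_size=75, seg_size=(150, 75), heatmap_variance=2.0,
            seg_threshold=0.5,
        ),
        backbone=BackboneConfig(width_scale=0.125),
        model=ModelConfig(attn_channels=64, fpn_channels=32, top_k=400,
                          zreduce_channels=16, mlp_hidden=(32, 32),
                          loc_channels=(4, 8, 16, 16)),
        schedule=TrainSchedule(epochs=100, batch_size=8),
        online_aug=OnlineAugmentParams(brightness=0.25, contrast=0.25),
        profile="tiny",
        seed=seed,
    ).validate()


def get_profile(name: str, seed: int = 0) -> RunConfig:
    if name == "reference":
        return reference_config(seed)
    if name == "tiny":
        return tiny_config(seed)
    raise ValueError(f"unknown profile {name!r}")
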