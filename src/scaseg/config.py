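"""Configuration dataclasses for every pipeline stage.

All tunable hyperparameters live here so that a run is fully described by a
single YAML file (see :class:`RunConfig`).  Each section round-trips through
``to_dict``/``from_dict``; :func:`load_run_config` / :func:`save_run_config`
handle the file I/O and :func:`config_hash` fingerprints a configuration for
provenance logging.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import yaml

GROUPS = ("patient", "preclinical", "control")

#: Cohort mean structure volumes in % of total intracranial volume used as
#: the default atrophy targets of the phantom generator, per group
#: (medulla, pons, mesencephalon).
DEFAULT_FRACTION_TARGETS: Dict[str, Dict[str, float]] = {
    "patient": {"medulla": 0.26, "pons": 0.47, "mesencephalon": 0.40},
    "preclinical": {"medulla": 0.29, "pons": 0.76, "mesencephalon": 0.44},
    "control": {"medulla": 0.31, "pons": 0.82, "mesencephalon": 0.48},
}

#: Mean intensity of each tissue class in the phantom T1 images
#: (arbitrary units, roughly [0, 1] before bias field and noise).
DEFAULT_INTENSITY_MEANS: Dict[str, float] = {
    "background": 0.02,
    "head": 0.45,
    "medulla": 0.70,
    "pons": 0.80,
    "mesencephalon": 0.60,
}

STRUCTURES = ("medulla", "pons", "mesencephalon")
LABEL_CODES = {"background": 0, "medulla": 1, "pons": 2, "mesencephalon": 3}


def _asdict(obj) -> dict:
    d = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, tuple):
            v = list(v)
        d[f.name] = v
    return d


@dataclass
class PhantomSpec:
    """Geometry, atrophy targets and image model of the synthetic cohort."""

    grid_shape: Tuple[int, int, int] = (96, 96, 112)
    spacing: Tuple[float, float, float] = (0.8, 0.8, 0.8)
    group_fraction_targets: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_FRACTION_TARGETS.items()}
    )
    relative_volume_noise: float = 0.05
    intensity_means: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_MEANS)
    )
    noise_sd: float = 0.03
    bias_amplitude: float = 0.2
    seed: int = 0

    def validate(self, roi_shape: Optional[Tuple[int, int, int]] = None) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.relative_volume_noise < 0 or self.noise_sd < 0:
            raise ValueError("noise parameters must be nonnegative")
        if not 0 <= self.bias_amplitude < 1:
            raise ValueError("bias_amplitude must be in [0, 1)")
        for g, targets in self.group_fraction_targets.items():
            total = sum(targets.values())
            if not all(0 < t < 5 for t in targets.values()) or total >= 5:
                raise ValueError(f"fraction targets for {g!r} outside (0, 5) %TICV")
        if roi_shape is not None and any(
                g < r for g, r in zip(self.grid_shape, roi_shape)):
            raise ValueError("grid_shape smaller than the ROI")

    to_dict = _asdict

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for k in ("grid_shape", "spacing"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class RoiBox:
    """Half-open crop box ``[start, start + shape)`` in voxel indices."""

    start: Tuple[int, int, int] = (8, 8, 8)
    shape: Tuple[int, int, int] = (80, 80, 96)

    def validate(self, full_shape: Tuple[int, int, int]) -> None:
        if any(s < 0 for s in self.start) or any(n <= 0 for n in self.shape):
            raise ValueError("invalid RoiBox")
        if any(s + n > f for s, n, f in zip(self.start, self.shape, full_shape)):
            raise ValueError("ROI exceeds volume bounds")

    to_dict = _asdict

    @classmethod
    def from_dict(cls, d: dict) -> "RoiBox":
        return cls(start=tuple(d["start"]), shape=tuple(d["shape"]))


@dataclass
class ModelConfig:
    """Architectural hyperparameters of the attention/inception 3D U-Net.

    ``parameter_count`` of the built network is a pure function of this
    config.  ``im_branch_fractions`` allocates the output width of every
    inception module over its four concatenated maps (three main-branch
    convolutions and the pooled 1x1x1 branch).
    """

    encoder_widths: Tuple[int, ...] = (32, 64, 128, 256, 512)
    n_classes: int = 4
    in_channels: int = 1
    input_shape: Tuple[int, int, int] = (80, 80, 96)
    im_branch_fractions: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    cam_reduction: int = 16
    cbam_stack: int = 3
    sam_channel_plan: Tuple[int, ...] = (2, 2, 1)
    dropout_rate: float = 0.2
    upsample_kernel: int = 2
    conv_bias: bool = True
    norm_affine: bool = True

    def validate(self) -> None:
        if len(self.encoder_widths) != 5:
            raise ValueError("expected 5 encoder widths (four poolings)")
        if abs(sum(self.im_branch_fractions) - 1.0) > 1e-9:
            raise ValueError("im_branch_fractions must sum to 1")
        for w in self.encoder_widths:
            for fr in self.im_branch_fractions:
                if abs(w * fr - round(w * fr)) > 1e-9 or round(w * fr) < 1:
                    raise ValueError(f"width {w} not divisible per branch fractions")
        if self.cbam_stack < 0:
            raise ValueError("cbam_stack must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.cam_reduction < 1:
            raise ValueError("cam_reduction must be >= 1")

    to_dict = _asdict

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("encoder_widths", "input_shape", "im_branch_fractions", "sam_channel_plan"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class AugmentConfig:
    """Rigid augmentation: rotations, integer shifts and left-right flips."""

    rotation_range_deg: float = 15.0
    translation_range_vox: int = 15
    flip_probability: float = 0.5
    copies_per_image: int = 40
    seed: int = 0

    def validate(self) -> None:
        if self.rotation_range_deg < 0 or self.copies_per_image < 0:
            raise ValueError("ranges must be nonnegative")
        if not 0 <= self.flip_probability <= 1:
            raise ValueError("flip_probability must be in [0, 1]")

    to_dict = _asdict

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentConfig":
        return cls(**d)


@dataclass
class TrainConfig:
    epochs: int = 250
    learning_rate: float = 1e-4
    batch_size: int = 1
    dice_smooth_eps: float = 1e-5
    loss_channels: str = "all"  # "all" | "foreground"
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss_channels not in ("all", "foreground"):
            raise ValueError("loss_channels must be 'all' or 'foreground'")

    to_dict = _asdict

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class MetricConfig:
    nsd_tolerance_mm: float = 1.0
    hd_percentile: float = 95.0

    def validate(self) -> None:
        if not 0 < self.hd_percentile <= 100:
            raise ValueError("hd_percentile must be in (0, 100]")
        if self.nsd_tolerance_mm <= 0:
            raise ValueError("nsd_tolerance_mm must be > 0")

    to_dict = _asdict

    @classmethod
    def from_dict(cls, d: dict) -> "MetricConfig":
        return cls(**d)


@dataclass
class RunConfig:
    """One flat configuration with a section per pipeline stage."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    roi: RoiBox = field(default_factory=RoiBox)
    model: ModelConfig = field(default_factory=ModelConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    metric: MetricConfig = field(default_factory=MetricConfig)
    seed: int = 0
    n_per_group: Dict[str, int] = field(
        default_factory=lambda: {"patient": 13, "preclinical": 7, "control": 5}
    )
    sara_coupling: float = 0.7

    def to_dict(self) -> dict:
        return {
            "phantom": self.phantom.to_dict(),
            "roi": self.roi.to_dict(),
            "model": self.model.to_dict(),
            "augment": self.augment.to_dict(),
            "train": self.train.to_dict(),
            "metric": self.metric.to_dict(),
            "seed": self.seed,
            "n_per_group": dict(self.n_per_group),
            "sara_coupling": self.sara_coupling,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            phantom=PhantomSpec.from_dict(d.get("phantom", {})),
            roi=RoiBox.from_dict(d["roi"]) if "roi" in d else RoiBox(),
            model=ModelConfig.from_dict(d.get("model", {})),
            augment=AugmentConfig.from_dict(d.get("augment", {})),
            train=TrainConfig.from_dict(d.get("train", {})),
            metric=MetricConfig.from_dict(d.get("metric", {})),
            seed=int(d.get("seed", 0)),
            n_per_group=dict(d.get("n_per_group", {"patient": 13, "preclinical": 7, "control": 5})),
            sara_coupling=float(d.get("sara_coupling", 0.7)),
        )


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_hash(cfg) -> str:
    """Short sha256 fingerprint of a config section or a full RunConfig."""
    payload = yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
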