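"""Pipeline-level configuration: one YAML file drives every subcommand.

The root ``seed`` deterministically re-seeds every stochastic stage (scene
generation, parameter init, data order, augmentation).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .errors import ConfigError
from .model import ModelConfig
from .synthetic import SceneConfig
from .train import TrainingSchedule


@dataclass
class MeasureConfig:
    outlier_k: float = 5.0
    adjacency_radius: float | None = None  # default: half median femur length
    asymmetry_tol: float = 0.25
    score_threshold: float = 0.5


@dataclass
class DatasetConfig:
    n_images: int = 140
    fractions: tuple = (100 / 140, 20 / 140, 20 / 140)


@dataclass
class PipelineConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    measure: MeasureConfig = field(default_factory=MeasureConfig)
    seed: int = 0

    def __post_init__(self):
        self.reseed(self.seed)

    def reseed(self, seed: int) -> None:
        """Derive per-stage seeds from the root seed."""
        self.seed = int(seed)
        self.scene.seed = self.seed
        self.model.seed = (self.seed + 1) % (2 ** 31)
        self.schedule.seed = (self.seed + 2) % (2 ** 31)
        if self.schedule.augment is not None:
            self.schedule.augment.seed = (self.seed + 3) % (2 ** 31)

    def validate(self) -> None:
        self.scene.validate()
        self.model.validate()
        self.schedule.validate()
        if self.schedule.augment is not None:
            self.schedule.augment.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{cls.__name__}: unknown fields {sorted(unknown)}")
    return cls(**data)


_SECTIONS = {"scene": SceneConfig, "model": ModelConfig,
             "schedule": TrainingSchedule, "dataset": DatasetConfig,
             "measure": MeasureConfig}


def load_config(path=None, overrides: list[str] | None = None) -> PipelineConfig:
    """Load a pipeline config from YAML, then apply ``a.b=c`` overrides."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"{path}: config must be a mapping")
            data = loaded
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.pop(name, {})
        if name == "schedule" and isinstance(section, dict) \
                and isinstance(section.get("augment"), dict):
            section = {**section,
                       "augment": _build(AugmentConfig, section["augment"])}
        kwargs[name] = _build(cls, section or {})
    seed = data.pop("seed", 0)
    if data:
        raise ConfigError(f"unknown top-level config keys {sorted(data)}")
    cfg = PipelineConfig(seed=int(seed), **kwargs)
    for ov in overrides or []:
        _apply_override(cfg, ov)
    cfg.reseed(cfg.seed)
    cfg.validate()
    return cfg


def _apply_override(cfg: PipelineConfig, expr: str) -> None:
    if "=" not in expr:
        raise ConfigError(f"override {expr!r} must be dotted.path=value")
    dotted, raw = expr.split("=", 1)
    value = yaml.safe_load(raw)
    obj = cfg
    parts = dotted.split(".")
    for part in parts[:-1]:
        if not hasattr(obj, part):
            raise ConfigError(f"unknown config path {dotted!r}")
        obj = getattr(obj, part)
    if not hasattr(obj, parts[-1]):
        raise ConfigError(f"unknown config path {dotted!r}")
    setattr(obj, parts[-1], value)


def desk_profile(seed: int = 0) -> PipelineConfig:
    """Desk-scale profile: tiny backbone, 140 synthetic 256x256 images
    (100 train / 20 val / 20 test, 1-2 mice each), shortened epoch budgets.

    The synthetic generator randomizes pose and placement per scene, so
    training-time augmentation keeps only the exact transforms (flips,
    brightness/contrast); resampling transforms would blur the endpoint
    gradients the keypoint head relies on at this scale.
    """
    cfg = PipelineConfig(
        scene=SceneConfig(image_width=256, image_height=256,
                          integer_keypoints=True),
        model=ModelConfig(backbone="tiny_fpn"),
        schedule=TrainingSchedule(
            detection_epochs=20, keypoint_epochs=85,
            milestones=[65, 78], patience=20, batch_size=4,
            augment=AugmentConfig(p_geometric=0.0, p_hflip=0.5, p_vflip=0.5,
                                  brightness_limit=0.1, contrast_limit=0.1)),
        dataset=DatasetConfig(n_images=140,
                              fractions=(100 / 140, 20 / 140, 20 / 140)),
        seed=seed)
    return cfg
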