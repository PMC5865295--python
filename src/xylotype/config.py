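"""Run configuration: one strict YAML file drives the whole pipeline.

Unknown keys are errors (a silently ignored typo in a hyperparameter is the
main reproducibility hazard), the canonical serialized form is hashed to
name the run directory, and the single global seed fans out to per-stage
seeds by stable hashing, so two configs that differ only in key order are
the same run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["RunConfig", "ConfigError", "derive_seed"]


class ConfigError(ValueError):
    """Invalid or unknown configuration field."""


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic 31-bit per-stage seed from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context} must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown field(s) in {context}: {', '.join(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class DatasetConfig:
    preset: str = "meliaceae10"  # {"meliaceae10", "three_class", "three_class_twins"}
    scale: float = 0.1
    image_size: int = 256
    image_dir: Optional[str] = None  # use pre-existing images instead of generating

    def validate(self) -> None:
        if self.preset not in ("meliaceae10", "three_class", "three_class_twins"):
            raise ConfigError(f"unknown dataset preset {self.preset!r}")
        if self.scale <= 0:
            raise ConfigError("dataset.scale must be > 0")
        if self.image_size < 32:
            raise ConfigError("dataset.image_size must be >= 32")


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: object = "preset"  # "preset" = per-class fractions, or float
    stratify_by: str = "species"
    unit: str = "image"

    def validate(self) -> None:
        if self.train_fraction != "preset" and not (
            isinstance(self.train_fraction, (int, float))
            and 0 < float(self.train_fraction) < 1
        ):
            raise ConfigError("split.train_fraction must be 'preset' or in (0, 1)")
        if self.stratify_by not in ("species", "none"):
            raise ConfigError("split.stratify_by must be 'species' or 'none'")
        if self.unit not in ("image", "specimen"):
            raise ConfigError("split.unit must be 'image' or 'specimen'")


@dataclass(frozen=True)
class PatchConfig:
    patch_height: int = 256
    patch_width: int = 96
    resized_height: int = 64
    resized_width: int = 24
    train_quota_per_class: int = 64
    test_quota_per_class: int = 24

    def validate(self) -> None:
        for name in (
            "patch_height",
            "patch_width",
            "resized_height",
            "resized_width",
            "train_quota_per_class",
            "test_quota_per_class",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"patch.{name} must be positive")


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "mini"
    pooling: str = "avg"
    dropout: float = 0.5
    pretrained: object = False

    def validate(self) -> None:
        if self.backbone not in ("mini", "vgg16_truncated"):
            raise ConfigError(f"unknown model.backbone {self.backbone!r}")
        if self.pooling not in ("avg", "max"):
            raise ConfigError("model.pooling must be 'avg' or 'max'")
        if not 0 <= self.dropout < 1:
            raise ConfigError("model.dropout must be in [0, 1)")


@dataclass(frozen=True)
class PhaseConfig:
    max_epochs: int = 30
    learning_rate: float = 1e-4
    momentum: float = 0.9
    decay: float = 0.0
    decay_mode: str = "lr"
    early_stop_patience: Optional[int] = None

    def validate(self, context: str) -> None:
        if self.max_epochs < 0:
            raise ConfigError(f"{context}.max_epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ConfigError(f"{context}.learning_rate must be > 0")
        if self.decay_mode not in ("lr", "weight"):
            raise ConfigError(f"{context}.decay_mode must be 'lr' or 'weight'")


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 8
    monitor: str = "val"  # {"val", "test", "none"}
    val_fraction: float = 0.25
    # Desk-scale defaults: the head learns from a randomly initialized
    # backbone, so phase 1 uses a stronger learning rate than the
    # reference protocol's 1e-4 (which presumes pretrained features).
    phase1: PhaseConfig = field(
        default_factory=lambda: PhaseConfig(
            max_epochs=30, learning_rate=1e-2, momentum=0.9
        )
    )
    phase2: PhaseConfig = field(
        default_factory=lambda: PhaseConfig(
            max_epochs=50,
            learning_rate=1e-3,
            decay=5e-4,
            early_stop_patience=10,
        )
    )

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ConfigError("training.batch_size must be >= 1")
        if self.monitor not in ("val", "test", "none"):
            raise ConfigError("training.monitor must be 'val', 'test' or 'none'")
        if not 0 < self.val_fraction < 0.5:
            raise ConfigError("training.val_fraction must be in (0, 0.5)")
        self.phase1.validate("training.phase1")
        self.phase2.validate("training.phase2")


@dataclass(frozen=True)
class EvaluationConfig:
    levels: tuple = ("species", "genus_clubbed", "genus")

    def validate(self) -> None:
        for level in self.levels:
            if level not in ("species", "genus_clubbed", "genus"):
                raise ConfigError(f"unknown evaluation level {level!r}")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    patch: PatchConfig = field(default_factory=PatchConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def validate(self) -> None:
        for section in (
            self.dataset,
            self.split,
            self.patch,
            self.model,
            self.training,
            self.evaluation,
        ):
            section.validate()

    # ------------------------------------------------------------- loading
    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown top-level field(s): {', '.join(unknown)}")
        kwargs: dict = {}
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        for name, sub_cls in (
            ("dataset", DatasetConfig),
            ("split", SplitConfig),
            ("patch", PatchConfig),
            ("model", ModelConfig),
            ("evaluation", EvaluationConfig),
        ):
            if name in data:
                sub = data[name]
                if name == "evaluation" and isinstance(sub, dict) and "levels" in sub:
                    sub = {**sub, "levels": tuple(sub["levels"])}
                kwargs[name] = _build(sub_cls, sub, name)
        if "training" in data:
            tr = dict(data["training"])
            for phase in ("phase1", "phase2"):
                if phase in tr:
                    tr[phase] = _build(PhaseConfig, tr[phase], f"training.{phase}")
            kwargs["training"] = _build(TrainingConfig, tr, "training")
        config = cls(**kwargs)
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    # ------------------------------------------------------------- hashing
    def to_canonical_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_canonical_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)
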