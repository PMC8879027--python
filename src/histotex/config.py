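"""Structured pipeline configuration with YAML round-trip.

The full profile mirrors the study's printed settings: G = 8 gray levels,
four orientations, the three ImageNet backbones, 200 epochs / validation
every 26 iterations / mini-batch 4 / learning rate 0.0003, and all six
classifiers.  A bundled ``smoke`` profile swaps in the ``tiny_cnn`` backbone
and a small synthetic dataset so the whole pipeline runs in minutes on one
CPU.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import CLASSIFIER_KINDS, CVProtocol, ClassifierSpec
from .datasets import SyntheticSpec
from .features import BACKBONE_REGISTRY, TrainingConfig
from .preprocessing import AugmentationConfig

__all__ = ["TextureConfig", "PipelineConfig"]


@dataclass(frozen=True)
class TextureConfig:
    """Texture-matrix and heatmap-rendering settings."""

    G: int = 8
    distance: int = 1
    render_mode: str = "matrix"
    colormap: str = "viridis"
    window: int = 32
    stride: int = 16

    def __post_init__(self) -> None:
        if self.G < 2:
            raise ValueError(f"G must be >= 2, got {self.G}")
        if self.distance < 1:
            raise ValueError(f"distance must be >= 1, got {self.distance}")
        if self.render_mode not in ("matrix", "tiled", "local"):
            raise ValueError(f"unknown render_mode {self.render_mode!r}")


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, resolvable from YAML."""

    dataset: SyntheticSpec | str = field(default_factory=SyntheticSpec)
    texture: TextureConfig = field(default_factory=TextureConfig)
    backbones: tuple[str, ...] = ("resnet101", "inception", "inception_resnet")
    training: TrainingConfig = field(default_factory=TrainingConfig)
    augmentation: AugmentationConfig = field(
        default_factory=lambda: AugmentationConfig(n_augments_per_image=2)
    )
    fusion_steps: tuple[str, ...] = ("textural", "full")
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS
    cv: CVProtocol = field(default_factory=CVProtocol)
    val_fraction: float = 0.2
    out_dir: str = "runs/histotex"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.backbones) - set(BACKBONE_REGISTRY)
        if unknown:
            raise ValueError(f"unknown backbones {sorted(unknown)}; registry: {BACKBONE_REGISTRY}")
        unknown = set(self.classifiers) - set(CLASSIFIER_KINDS)
        if unknown:
            raise ValueError(f"unknown classifiers {sorted(unknown)}; kinds: {CLASSIFIER_KINDS}")
        bad = set(self.fusion_steps) - {"textural", "full"}
        if bad:
            raise ValueError(f"unknown fusion steps {sorted(bad)}")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError(f"val_fraction must be in (0, 1), got {self.val_fraction}")

    # -- seed derivation ------------------------------------------------
    def dataset_seed(self) -> int:
        return (self.seed * 7 + 1) % (2**31)

    def training_seed(self) -> int:
        return (self.seed * 7 + 2) % (2**31)

    def classifier_seed(self) -> int:
        return (self.seed * 7 + 3) % (2**31)

    def resolved_dataset(self) -> SyntheticSpec | str:
        if isinstance(self.dataset, SyntheticSpec):
            return dataclasses.replace(self.dataset, seed=self.dataset_seed())
        return self.dataset

    def resolved_training(self) -> TrainingConfig:
        return dataclasses.replace(self.training, seed=self.training_seed())

    def classifier_spec(self, kind: str) -> ClassifierSpec:
        return ClassifierSpec(kind=kind, seed=self.classifier_seed())

    def resolved_cv(self) -> CVProtocol:
        return dataclasses.replace(self.cv, seed=self.classifier_seed())

    # -- profiles -------------------------------------------------------
    @classmethod
    def smoke(cls, out_dir: str = "runs/smoke", seed: int = 0, n_per_class: int = 8) -> "PipelineConfig":
        """Desk-scale profile: tiny backbone, small synthetic dataset."""
        return cls(
            dataset=SyntheticSpec(
                n_per_class=(n_per_class,) * 4, image_size=(64, 64), separability=1.0
            ),
            backbones=("tiny_cnn",),
            training=TrainingConfig(epochs=30),
            augmentation=AugmentationConfig(n_augments_per_image=0),
            cv=CVProtocol(k=4),
            out_dir=out_dir,
            seed=seed,
        )

    # -- YAML round-trip ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.dataset, SyntheticSpec):
            d["dataset"] = {"synthetic": dataclasses.asdict(self.dataset)}
        else:
            d["dataset"] = {"manifest": str(self.dataset)}
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ds = d.get("dataset", {})
        if "synthetic" in ds:
            syn = dict(ds["synthetic"])
            for key in ("n_per_class", "image_size"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            syn["texture_params"] = syn.get("texture_params") or {}
            d["dataset"] = SyntheticSpec(**syn)
        elif "manifest" in ds:
            d["dataset"] = str(ds["manifest"])
        if "texture" in d and isinstance(d["texture"], dict):
            d["texture"] = TextureConfig(**d["texture"])
        if "training" in d and isinstance(d["training"], dict):
            d["training"] = TrainingConfig(**d["training"])
        if "augmentation" in d and isinstance(d["augmentation"], dict):
            aug = dict(d["augmentation"])
            for key in ("translation_range", "scale_range", "shear_range"):
                if key in aug:
                    aug[key] = tuple(aug[key])
            d["augmentation"] = AugmentationConfig(**aug)
        if "cv" in d and isinstance(d["cv"], dict):
            d["cv"] = CVProtocol(**d["cv"])
        for key in ("backbones", "fusion_steps", "classifiers"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert tuples to lists so YAML stays clean."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
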