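"""Run configuration: YAML loading with strict validation.

Parsing is fail-fast: unknown keys are rejected by name rather than
silently defaulted, because a silently misspelled key corrupts ablation
comparisons.  An empty file yields the standard defaults (batch size 8,
learning rate 5e-4, loss weights 0.4/0.25/0.35, θ = 0.5, 50-d type
embeddings/prototypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .classifiers import LossWeights
from .training import TrainConfig

__all__ = ["EncoderConfig", "RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class EncoderConfig:
    kind: str = "tiny"
    d: int = 64
    n_layers: int = 2
    n_heads: int = 4
    ffn_dim: int = 128
    head_hidden: int = 64


@dataclass
class RunConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    sharing_mode: str = "none"
    augmentation_mode: str = "entity_marker"
    classifier_mode: str = "multi"
    paradigm: str = "multi_corpora"
    train: TrainConfig = field(default_factory=TrainConfig)
    theta: float = 0.5
    aux_dim: int = 50
    seed: int = 0
    output_dir: str = "runs"
    conditional_eval: bool = True

    def validate(self) -> "RunConfig":
        from .augmentation import AUGMENTATION_MODES
        from .encoders import EncoderBundle
        from .synthetic import PARADIGMS
        if self.sharing_mode not in EncoderBundle.SHARING_MODES:
            raise ConfigError(f"unknown sharing_mode {self.sharing_mode!r}")
        if self.augmentation_mode not in AUGMENTATION_MODES:
            raise ConfigError(f"unknown augmentation_mode {self.augmentation_mode!r}")
        if self.classifier_mode not in ("single", "multi"):
            raise ConfigError(f"unknown classifier_mode {self.classifier_mode!r}")
        if self.paradigm not in PARADIGMS:
            raise ConfigError(f"unknown paradigm {self.paradigm!r}")
        if self.augmentation_mode == "entity_marker" and self.sharing_mode == "hard":
            raise ConfigError(
                "invalid combination: entity_marker augmentation with hard "
                "sharing (the NER branch needs the raw sentence while the RE "
                "branch needs the marked one)")
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigError("theta must be in [0, 1]")
        return self

    def model_kwargs(self) -> dict:
        return dict(sharing_mode=self.sharing_mode,
                    augmentation_mode=self.augmentation_mode,
                    classifier_mode=self.classifier_mode,
                    d=self.encoder.d, n_layers=self.encoder.n_layers,
                    n_heads=self.encoder.n_heads, ffn_dim=self.encoder.ffn_dim,
                    head_hidden=self.encoder.head_hidden, theta=self.theta,
                    aux_dim=self.aux_dim, seed=self.seed)


def _build(cls, data: dict, where: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")
    kwargs = {}
    for key, value in data.items():
        if key == "encoder":
            kwargs[key] = _build(EncoderConfig, value or {}, "encoder")
        elif key == "train":
            value = dict(value or {})
            if "weights" in value:
                w = value.pop("weights")
                unknown_w = set(w) - {"sp", "et", "re"}
                if unknown_w:
                    raise ConfigError(f"unknown key(s) {sorted(unknown_w)} in train.weights")
                value["weights"] = LossWeights(**w)
            kwargs[key] = _build(TrainConfig, value, "train")
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where} section: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file → defaults)."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return _build(RunConfig, data, "run config").validate()
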