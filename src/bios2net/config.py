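"""Run configuration: a small YAML schema tying the pipeline together.

Schema (all sections optional; unknown fields are rejected)::

    model:
      preset: default | reduced      # architecture scale
      n_points: 1024
      sequence_on: true
      structure_on: true
      temporal_on: true
      seq_filters_per_branch: 16
      temporal_filters_per_branch: 16
      head_widths: [512, 256]
    training:
      epochs: 60
      batch_size: 32
      learning_rate: 0.001
    augmentation:
      rotation: true
      scale_range: [0.9, 1.1]
      translation_range: 0.1
      jitter_sigma: 0.005
      jitter_clip: 0.02
    features:
      asa_points: 960
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .nn.model import ModelConfig
from .sampling import AugmentationConfig
from .training import TrainConfig


class RunConfigError(ValueError):
    """Raised for unknown or invalid configuration fields."""


_MODEL_FIELDS = {
    "preset", "n_points", "sequence_on", "structure_on", "temporal_on",
    "seq_filters_per_branch", "temporal_filters_per_branch", "head_widths",
}
_TRAIN_FIELDS = {"epochs", "batch_size", "learning_rate"}
_AUG_FIELDS = {"rotation", "scale_range", "translation_range",
               "jitter_sigma", "jitter_clip"}
_FEATURE_FIELDS = {"asa_points"}


@dataclass
class RunConfig:
    model: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    augmentation: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)

    def model_config(self, n_classes: int) -> ModelConfig:
        opts = dict(self.model)
        preset = opts.pop("preset", "reduced")
        if "head_widths" in opts:
            opts["head_widths"] = tuple(opts["head_widths"])
        factory = {"default": ModelConfig.default,
                   "reduced": ModelConfig.reduced}.get(preset)
        if factory is None:
            raise RunConfigError(f"unknown model preset {preset!r}")
        return factory(n_classes, **opts)

    def train_config(self) -> TrainConfig:
        aug_opts = dict(self.augmentation)
        if "scale_range" in aug_opts:
            aug_opts["scale_range"] = tuple(aug_opts["scale_range"])
        return TrainConfig(
            **self.training,
            augmentation=AugmentationConfig(**aug_opts),
            **{k: v for k, v in self.features.items()},
        )


def _check_fields(section: str, data: dict, allowed: set[str]) -> None:
    for key in data:
        if key not in allowed:
            raise RunConfigError(
                f"unknown field {key!r} in config section {section!r}")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise RunConfigError("config root must be a mapping")
    known = {"model", "training", "augmentation", "features"}
    for key in raw:
        if key not in known:
            raise RunConfigError(f"unknown config section {key!r}")
    cfg = RunConfig(**{k: raw.get(k, {}) or {} for k in known})
    _check_fields("model", cfg.model, _MODEL_FIELDS)
    _check_fields("training", cfg.training, _TRAIN_FIELDS)
    _check_fields("augmentation", cfg.augmentation, _AUG_FIELDS)
    _check_fields("features", cfg.features, _FEATURE_FIELDS)
    return cfg
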