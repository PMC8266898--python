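"""YAML run-configuration loading.

A single file with optional sections ``data``, ``architecture``,
``training``, ``augmentation`` and ``grid``; every field defaults to the
protocol's optimum, so an empty file is a valid configuration.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .data import AugmentationConfig
from .networks import ArchitectureConfig
from .training import TrainingConfig


def load_config(path) -> dict:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return raw


def architecture_from(cfg: dict) -> ArchitectureConfig:
    section = dict(cfg.get("architecture", {}))
    if "dilation_rates" in section:
        section["dilation_rates"] = tuple(section["dilation_rates"])
    return ArchitectureConfig(**section)


def augmentation_from(cfg: dict) -> AugmentationConfig | None:
    section = cfg.get("augmentation")
    if section is None:
        return None
    section = dict(section)
    for key in ("rotations", "shear_limit", "color_jitter", "gaussian_blur_limit",
                "gauss_noise_var"):
        if key in section and section[key] is not None:
            section[key] = tuple(section[key])
    return AugmentationConfig(**section)


def training_from(cfg: dict) -> TrainingConfig:
    section = dict(cfg.get("training", {}))
    aug = augmentation_from(cfg)
    if aug is not None:
        section.setdefault("augmentation", True)
        section["augmentation_config"] = aug
    return TrainingConfig(**section)


def grid_from(cfg: dict) -> dict:
    grid = dict(cfg.get("grid", {}))
    for key in ("dilation_rates",):
        if key in grid:
            grid[key] = [tuple(v) for v in grid[key]]
    return grid
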