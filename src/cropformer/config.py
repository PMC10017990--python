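"""YAML configuration schema and deterministic seed management.

One YAML file drives the whole pipeline, mirroring the two natural
hyperparameter groups (network structure, training optimization) plus the
simulation and scenario settings.  Every stochastic stage receives a seed
derived from a single master seed by fixed offsets, so a run is
reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

from .classification import FinetuneConfig
from .encoder import SMALL_PROFILE, ModelConfig
from .pretraining import PretrainConfig
from .simulate import (
    CropClassSpec,
    SimConfig,
    default_four_classes,
    imbalanced_eight_classes,
)

__all__ = [
    "ConfigError",
    "load_config",
    "model_config_from_dict",
    "pretrain_config_from_dict",
    "finetune_config_from_dict",
    "sim_config_from_dict",
    "derive_seed",
    "apply_overrides",
    "write_manifest",
]

# fixed offsets deriving stage seeds from the master seed
SEED_OFFSETS = {"simulate": 0, "pretrain": 1, "finetune": 2, "scenario": 3,
                "split": 4, "predict": 5}
_SEED_MOD = 2**31 - 1


class ConfigError(ValueError):
    """A config file violates the schema; the message names the key."""


def derive_seed(master_seed: int, stage: str) -> int:
    if stage not in SEED_OFFSETS:
        raise ConfigError(f"unknown seed stage {stage!r}")
    return int((int(master_seed) + SEED_OFFSETS[stage]) % _SEED_MOD)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"invalid YAML in {path}: {e}") from e
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return cfg


def _build(cls, section: dict, name: str, defaults: Any = None):
    base = dataclasses.asdict(defaults) if defaults is not None else {}
    allowed = {f.name for f in dataclasses.fields(cls)}
    for key, val in section.items():
        if key not in allowed:
            raise ConfigError(f"{name}.{key}: unknown key")
        base[key] = val
    try:
        return cls(**base)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{name}: {e}") from e


def model_config_from_dict(section: dict) -> ModelConfig:
    section = dict(section or {})
    profile = section.pop("profile", "full")
    if profile not in ("full", "small"):
        raise ConfigError(f"model.profile: unknown profile {profile!r}")
    base = SMALL_PROFILE if profile == "small" else ModelConfig()
    return _build(ModelConfig, section, "model", defaults=base)


def pretrain_config_from_dict(section: dict) -> PretrainConfig:
    return _build(PretrainConfig, dict(section or {}), "pretrain")


def finetune_config_from_dict(section: dict) -> FinetuneConfig:
    return _build(FinetuneConfig, dict(section or {}), "finetune")


def sim_config_from_dict(section: dict) -> SimConfig:
    section = dict(section or {})
    preset = section.pop("preset", "four_class")
    if preset == "four_class":
        classes, counts = tuple(default_four_classes()), None
    elif preset == "eight_class_imbalanced":
        specs, counts = imbalanced_eight_classes()
        classes = tuple(specs)
    else:
        raise ConfigError(f"simulate.preset: unknown preset {preset!r}")
    if "classes" in section:
        classes = tuple(
            _build(CropClassSpec, c, f"simulate.classes[{i}]")
            for i, c in enumerate(section.pop("classes"))
        )
        counts = None
    if "n_per_class" not in section:
        section["n_per_class"] = tuple(counts) if counts is not None \
            else tuple([250] * len(classes))
    section["classes"] = classes
    section["n_per_class"] = tuple(section["n_per_class"])
    return _build(SimConfig, section, "simulate")


def apply_overrides(cfg: dict, overrides: list[str]) -> dict:
    """Apply ``dotted.key=value`` command-line overrides to a config dict."""
    out = json.loads(json.dumps(cfg))  # deep copy of plain data
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} must look like key=value")
        dotted, raw = item.split("=", 1)
        value = yaml.safe_load(raw)
        node = out
        keys = dotted.split(".")
        for k in keys[:-1]:
            node = node.setdefault(k, {})
            if not isinstance(node, dict):
                raise ConfigError(f"override {dotted!r}: {k} is not a mapping")
        node[keys[-1]] = value
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, command: str, config_echo: dict,
                   seeds: dict[str, int], outputs: list[str | Path]) -> None:
    """Record everything needed to regenerate the listed artifacts."""
    from . import __version__

    manifest = {
        "command": command,
        "version": __version__,
        "config": config_echo,
        "seeds": seeds,
        "outputs": {str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
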