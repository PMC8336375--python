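"""Run configuration: one YAML document drives every experiment.

A RunConfig bundles the dataset paths, the network/training/CV/
augmentation settings, the feature and classifier selections and the
master seed.  It round-trips losslessly through YAML, and its SHA-256
hash is stamped into every run log so any artifact can be traced to the
exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .augment import AugmentationPolicy
from .baselines import CLASSIFIER_NAMES
from .crossval import CVProtocol
from .features import FEATURE_SETS
from .model import VARIANTS, NetConfig
from .training import TrainConfig


class ConfigSchemaError(ValueError):
    pass


@dataclass
class RunConfig:
    manifest: str = ""
    output_dir: str = "runs"
    net: NetConfig = field(default_factory=NetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    cv: CVProtocol = field(default_factory=CVProtocol)
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    feature_sets: tuple[str, ...] = FEATURE_SETS
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    variant: str = "full"
    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigSchemaError(f"variant: must be one of {VARIANTS}")
        for s in self.feature_sets:
            if s not in FEATURE_SETS:
                raise ConfigSchemaError(f"feature_sets: unknown set {s!r}")
        for c in self.classifiers:
            if c not in CLASSIFIER_NAMES:
                raise ConfigSchemaError(f"classifiers: unknown classifier {c!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigSchemaError("test_fraction: must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            if "net" in d and isinstance(d["net"], dict):
                d["net"] = NetConfig.from_dict(d["net"])
            if "train" in d and isinstance(d["train"], dict):
                d["train"] = TrainConfig(**d["train"])
            if "cv" in d and isinstance(d["cv"], dict):
                d["cv"] = CVProtocol(**d["cv"])
            if "augmentation" in d and isinstance(d["augmentation"], dict):
                aug = dict(d["augmentation"])
                if aug.get("rescale_range") is not None:
                    aug["rescale_range"] = tuple(aug["rescale_range"])
                d["augmentation"] = AugmentationPolicy(**aug)
            for key in ("feature_sets", "classifiers"):
                if key in d and d[key] is not None:
                    d[key] = tuple(d[key])
            return cls(**d)
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ConfigSchemaError):
                raise
            raise ConfigSchemaError(f"invalid run config: {exc}") from exc

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text())
        if not isinstance(loaded, dict):
            raise ConfigSchemaError(f"config {path} is not a mapping")
        return cls.from_dict(loaded)

    def config_hash(self) -> str:
        canon = json.dumps(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _plain(obj):
    """Tuples to lists, recursively, for clean YAML/JSON."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
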