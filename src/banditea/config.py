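"""YAML run configuration with validated defaults.

A config file is a YAML mapping with optional sections ``fingerprint``,
``clustering``, ``params``, ``trial``, ``curation`` and ``ea`` plus a
top-level ``seed``.  Every omitted key takes the package default (kernel
width 0.2 A, bin 0.5 A, r_max 8 A, clustering threshold 0.026 with minimum
cluster size 20, initial weight 100, 5x50x20 batch budget, learning
parameters 79/3/19/68).  Unknown keys and invalid values raise
:class:`ConfigError` naming the key.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .agent import LearningParams
from .ea import CurationConfig, EaConfig
from .fingerprints import FingerprintConfig
from .surrogate import TrialConfig

__all__ = ["ConfigError", "RunConfig", "load_config"]

DEFAULT_CLUSTER_THRESHOLD = 0.026
DEFAULT_MIN_CLUSTER_SIZE = 20


class ConfigError(ValueError):
    """Invalid or unknown configuration entry."""


@dataclass
class RunConfig:
    seed: int = 0
    fingerprint: FingerprintConfig = field(default_factory=FingerprintConfig)
    clustering_threshold: float = DEFAULT_CLUSTER_THRESHOLD
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
    params: LearningParams = field(default_factory=LearningParams)
    trial: TrialConfig = field(default_factory=TrialConfig)
    curation: CurationConfig = field(default_factory=CurationConfig)
    ea: EaConfig = field(default_factory=EaConfig)

    def __post_init__(self) -> None:
        if self.clustering_threshold <= 0:
            raise ConfigError(
                f"clustering.threshold must be > 0, got {self.clustering_threshold}"
            )
        if self.min_cluster_size < 1:
            raise ConfigError(
                f"clustering.min_size must be >= 1, got {self.min_cluster_size}"
            )


def _build_section(cls, section: str, data: Mapping[str, Any]):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown config key {section}.{sorted(unknown)[0]}")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}") from exc


_SECTIONS = {
    "fingerprint": FingerprintConfig,
    "params": LearningParams,
    "trial": TrialConfig,
    "curation": CurationConfig,
    "ea": EaConfig,
}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration (``None``/empty -> defaults)."""
    raw: Any = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if raw is None:
            raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config file must contain a YAML mapping")
    known_top = set(_SECTIONS) | {"seed", "clustering"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown config key {sorted(unknown)[0]}")
    kwargs: dict[str, Any] = {}
    if "seed" in raw:
        try:
            kwargs["seed"] = int(raw["seed"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid value for seed: {raw['seed']!r}") from exc
    clustering = raw.get("clustering", {}) or {}
    if not isinstance(clustering, Mapping):
        raise ConfigError("clustering section must be a mapping")
    unknown = set(clustering) - {"threshold", "min_size"}
    if unknown:
        raise ConfigError(f"unknown config key clustering.{sorted(unknown)[0]}")
    if "threshold" in clustering:
        kwargs["clustering_threshold"] = float(clustering["threshold"])
    if "min_size" in clustering:
        kwargs["min_cluster_size"] = int(clustering["min_size"])
    for section, cls in _SECTIONS.items():
        if section in raw:
            data = raw[section] or {}
            if not isinstance(data, Mapping):
                raise ConfigError(f"section {section!r} must be a mapping")
            if section == "ea" and "fingerprint" in data:
                data = dict(data)
                data["fingerprint"] = _build_section(
                    FingerprintConfig, "ea.fingerprint", data["fingerprint"]
                )
            kwargs[section] = _build_section(cls, section, data)
    return RunConfig(**kwargs)
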