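"""Declarative run configuration with strict schema validation.

An empty config yields the documented defaults; unknown keys are rejected by
name. The materialized config is echoed into every run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """The configuration violates the schema; the message names the key."""


@dataclass
class FilterConfig:
    vaf_min: float = 0.10
    max_indel: int = 5
    apply_vaf_filter: bool = True  # may be disabled per cohort dialect


@dataclass
class CopyNumberConfig:
    gain_thr: float = 0.3
    loss_thr: float = -0.3
    cap: float = 1.5
    min_overlap: float = 0.25
    gain_margin: float = 0.0
    hom_loss_max: float = 0.0


@dataclass
class ModelConfig:
    n_iter: int = 10_000
    checkpoint_every: int = 100
    repeats: int = 5
    grid: str = "default"  # "default" | "small"
    top_k: int = 10
    expression_threshold: float = 0.0
    include_training_genes: bool = False  # validation-cohort mode
    reuse_scaling: bool = True  # scale validation cohorts with stored params


@dataclass
class PathwayConfig:
    min_size: int = 10
    max_size: int = 500
    excluded_levels: list[int] = field(default_factory=lambda: [1, 2])
    fdr_threshold: float = 0.01
    k_min: int = 3
    k_max: int = 20


@dataclass
class GermlineConfig:
    z: float = 2.6
    hom_min: float = 0.95
    maf_inflation_max: float = 0.10
    rare_max: float = 0.01


@dataclass
class Config:
    filters: FilterConfig = field(default_factory=FilterConfig)
    copy_number: CopyNumberConfig = field(default_factory=CopyNumberConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    pathways: PathwayConfig = field(default_factory=PathwayConfig)
    germline: GermlineConfig = field(default_factory=GermlineConfig)
    na_sentinel: str = "NA"

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "filters": FilterConfig,
    "copy_number": CopyNumberConfig,
    "model": ModelConfig,
    "pathways": PathwayConfig,
    "germline": GermlineConfig,
}


def _build_section(name: str, cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a YAML config; ``None`` or an empty file gives defaults."""
    data = {}
    if path is not None:
        raw = Path(path).read_text()
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS) - {"na_sentinel"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    sections = {
        name: _build_section(name, cls, data.get(name, {}) or {})
        for name, cls in _SECTIONS.items()
    }
    return Config(na_sentinel=data.get("na_sentinel", "NA"), **sections)
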