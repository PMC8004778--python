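"""Run configuration: one YAML file drives a full experiment.

All defaults are materialized on load, unknown keys are rejected by name, and
the materialized configuration round-trips unchanged, so a run directory's
config echo is sufficient to re-run the experiment bit-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classifiers import CLASSIFIER_NAMES
from .errors import ConfigError
from .synthetic import BankExtractorSpec, FeatureBankConfig, PhantomConfig

__all__ = ["RunConfig", "load_config", "save_config"]

_DATA_SOURCES = ("feature_bank", "phantoms", "feature_dir")


@dataclass
class RunConfig:
    """Fully materialized experiment configuration."""

    seed: int = 0
    source: str = "feature_bank"
    k: int = 3
    mode: str = "holdout"  # or "paper_faithful"
    train_fraction: float = 0.8
    stratified: bool = False
    grid_scale: str = "reduced"  # or "full"
    augment: str = "none"  # "none" | "exhaustive" | "random"
    feature_dir: str | None = None
    grids: dict = field(default_factory=dict)  # per-classifier grid overrides
    feature_bank: dict = field(default_factory=dict)
    phantoms: dict = field(default_factory=dict)

    def bank_config(self) -> FeatureBankConfig:
        fb = dict(self.feature_bank)
        extractors = tuple(
            BankExtractorSpec(
                **{**e, "separated_classes": tuple(e["separated_classes"])}
                if e.get("separated_classes") is not None
                else e
            )
            for e in fb.pop("extractors", [])
        )
        return FeatureBankConfig(seed=self.seed, extractors=extractors, **fb)

    def phantom_config(self) -> PhantomConfig:
        ph = dict(self.phantoms)
        ph.pop("n_per_class", None)
        for key in ("image_size", "tumor_radius_range"):
            if key in ph:
                ph[key] = tuple(ph[key])
        if "classes" in ph:
            ph["classes"] = tuple(ph["classes"])
        if "brain_axes" in ph:
            ph["brain_axes"] = tuple(tuple(ax) for ax in ph["brain_axes"])
        return PhantomConfig(seed=self.seed, **ph)

    def to_dict(self) -> dict:
        return asdict(self)


_DEFAULTS = RunConfig().to_dict()


def load_config(path: str | Path) -> RunConfig:
    """Load, validate, and default-fill a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = sorted(set(raw) - set(_DEFAULTS))
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    merged = {**_DEFAULTS, **raw}
    cfg = RunConfig(**merged)
    if cfg.source not in _DATA_SOURCES:
        raise ConfigError(f"invalid value for 'source': {cfg.source!r}")
    if cfg.mode not in ("holdout", "paper_faithful"):
        raise ConfigError(f"invalid value for 'mode': {cfg.mode!r}")
    if cfg.grid_scale not in ("reduced", "full"):
        raise ConfigError(f"invalid value for 'grid_scale': {cfg.grid_scale!r}")
    if cfg.augment not in ("none", "exhaustive", "random"):
        raise ConfigError(f"invalid value for 'augment': {cfg.augment!r}")
    if not (0.0 < cfg.train_fraction < 1.0):
        raise ConfigError("invalid value for 'train_fraction': must be in (0, 1)")
    if cfg.k < 1:
        raise ConfigError("invalid value for 'k': must be >= 1")
    for name in cfg.grids:
        if name not in CLASSIFIER_NAMES:
            raise ConfigError(f"grid override for unknown classifier: {name!r}")
    if cfg.source == "feature_dir" and not cfg.feature_dir:
        raise ConfigError("source 'feature_dir' requires the 'feature_dir' key")
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
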