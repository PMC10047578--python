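"""YAML-backed run configuration.

Unknown keys are rejected so a typo in a config file fails loudly instead
of silently running with defaults.  Every CLI run persists the fully
resolved configuration next to its results.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .exceptions import ParameterError

__all__ = ["RunConfig", "load_config", "resolve_config"]


@dataclass
class PrepConfig:
    ng: int = 8


@dataclass
class GlcmConfig:
    distance: int = 1


@dataclass
class HogSection:
    bins: int = 9
    cell: int = 8
    block: int = 2
    components: int = 20
    paper_mode: bool = False


@dataclass
class FusionConfig:
    block: str = "hybrid"


@dataclass
class AugmentSection:
    rotation_deg: float = 15.0
    width_shift: float = 0.2
    height_shift: float = 0.2
    shear: float = 0.2
    horizontal_flip: bool = True
    vertical_flip: bool = True
    n_per_image: int = 4
    seed: int = 0


@dataclass
class ClassifySection:
    classifiers: list[str] = field(
        default_factory=lambda: [
            "naive_bayes",
            "bayes_net",
            "random_tree",
            "random_forest",
            "decision_table",
            "logistic",
        ]
    )
    k_folds: int = 10
    seed: int = 0


@dataclass
class RunConfig:
    prep: PrepConfig = field(default_factory=PrepConfig)
    glcm: GlcmConfig = field(default_factory=GlcmConfig)
    hog: HogSection = field(default_factory=HogSection)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    augment: AugmentSection = field(default_factory=AugmentSection)
    classify: ClassifySection = field(default_factory=ClassifySection)


_SECTIONS = {f.name: f.type for f in fields(RunConfig)}


def _build_section(cls, data: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ParameterError(
            f"unknown config key(s) {sorted(unknown)} under {path!r}"
        )
    return cls(**data)


def load_config(path) -> RunConfig:
    """Parse a YAML config file, rejecting unknown keys at any level."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config file {path!s} must contain a mapping")
    cfg = RunConfig()
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ParameterError(f"unknown config section(s) {sorted(unknown)}")
    for name, data in raw.items():
        if not isinstance(data, dict):
            raise ParameterError(f"config section {name!r} must be a mapping")
        setattr(cfg, name, _build_section(type(getattr(cfg, name)), data, name))
    return cfg


def resolve_config(cfg: RunConfig) -> dict:
    """The fully resolved configuration as a plain dict (for persistence)."""
    return asdict(cfg)
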