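"""Pipeline configuration: defaults, YAML loading, validation, round-trip dump.

Absent keys take the pipeline defaults (4:20 sliding window, leading/trailing
Q3, minimum length 50, minimum 8 repeat copies for every motif size 2-6);
unknown keys are rejected by name so typos cannot silently disable a filter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .palfilter import FilterToggles
from .primerdesign import PrimerParams
from .readtrim import TrimConfig
from .ssrfind import DEFAULT_MAX_GAP, DEFAULT_MIN_COPIES, MOTIF_MAX, MOTIF_MIN


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


@dataclass
class SsrConfig:
    """SSR-detection settings; ``min_copies`` may be one number or per motif size."""

    min_copies: int | dict[int, int] = DEFAULT_MIN_COPIES
    max_gap: int = DEFAULT_MAX_GAP

    def __post_init__(self) -> None:
        if isinstance(self.min_copies, Mapping):
            self.min_copies = {int(k): int(v) for k, v in self.min_copies.items()}
            missing = set(range(MOTIF_MIN, MOTIF_MAX + 1)) - set(self.min_copies)
            if missing:
                raise ValueError(f"min_copies missing motif sizes {sorted(missing)}")
            values = self.min_copies.values()
        else:
            values = [self.min_copies]
        if any(v < 2 for v in values):
            raise ValueError("min_copies must be >= 2")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")

    def copies_by_size(self) -> dict[int, int]:
        if isinstance(self.min_copies, Mapping):
            return dict(self.min_copies)
        return {k: self.min_copies for k in range(MOTIF_MIN, MOTIF_MAX + 1)}


@dataclass
class AssemblyConfig:
    enabled: bool = True
    min_overlap: int = 15
    min_identity: float = 0.9
    max_primer_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")
        if self.max_primer_mismatches not in (0, 1):
            raise ValueError("max_primer_mismatches must be 0 or 1")


@dataclass
class PipelineConfig:
    """Complete, validated configuration of one pipeline run."""

    in1: str = ""
    in2: str = ""
    output_dir: str = "satellite_miner_out"
    quality_offset: int = 33
    trim: TrimConfig = field(default_factory=TrimConfig)
    ssr: SsrConfig = field(default_factory=SsrConfig)
    primer: PrimerParams = field(default_factory=PrimerParams)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    filters: FilterToggles = field(default_factory=FilterToggles)
    count_reverse_complement: bool = True
    write_merged_reads: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.quality_offset not in (33, 64):
            raise ValueError("quality_offset must be 33 or 64")


_SECTIONS = {
    "trim": TrimConfig,
    "ssr": SsrConfig,
    "primer": PrimerParams,
    "assembly": AssemblyConfig,
    "filters": FilterToggles,
}

_SCALARS = {
    "in1",
    "in2",
    "output_dir",
    "quality_offset",
    "count_reverse_complement",
    "write_merged_reads",
    "seed",
    "log_level",
}


def _build_section(cls: type, name: str, data: Mapping[str, Any]) -> Any:
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    kwargs = dict(data)
    if "step_order" in kwargs and kwargs["step_order"] is not None:
        kwargs["step_order"] = tuple(kwargs["step_order"])
    if "adapters" in kwargs and kwargs["adapters"] is not None:
        kwargs["adapters"] = tuple(kwargs["adapters"])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {name!r}: {exc}") from exc


def config_from_dict(data: Mapping[str, Any] | None) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig`; unknown keys are rejected."""
    data = dict(data or {})
    unknown = set(data) - _SCALARS - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data.pop(name)
            if section is None:
                section = {}
            if not isinstance(section, Mapping):
                raise ConfigError(f"section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, name, section)
    kwargs.update(data)
    try:
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def config_to_dict(cfg: PipelineConfig) -> dict[str, Any]:
    """Plain-dict form of a config; round-trips through :func:`config_from_dict`."""
    out: dict[str, Any] = {}
    for f in fields(cfg):
        value = getattr(cfg, f.name)
        if f.name in _SECTIONS:
            section = dataclasses.asdict(value)
            for key, val in section.items():
                if isinstance(val, tuple):
                    section[key] = list(val)
            out[f.name] = section
        else:
            out[f.name] = value
    return out


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config file; an empty file yields the all-defaults config."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(data)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
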