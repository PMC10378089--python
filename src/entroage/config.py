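"""Run configuration: nested YAML with strict key validation.

Sections mirror the library modules::

    seed: 0
    out_dir: results
    verbosity: 1
    kl:        {base: 10.0, mode: normalized, floor: 1.0e-12}
    kinetic:   {nx: 64, nxi: 32, xi_max: 8.0, L: 1.0, tau: 0.1,
                tol: 1.0e-8, max_iter: 10000}
    simulation: any AgingSimConfig field
    allometry: {heartbeat: 0.1, metabolic_time: 3.0,
                beats_per_lifetime: 1.0e9, lifetime_correction: 1.0}

Unknown keys are rejected by name; every value is validated against its
module's domain before any computation runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .simulate import AgingSimConfig


@dataclass
class KLConfig:
    base: float = 10.0
    mode: str = "normalized"
    floor: float = 1e-12

    def __post_init__(self):
        if not (self.base > 1):
            raise ConfigError("kl.base must exceed 1")
        if self.mode not in ("normalized", "raw"):
            raise ConfigError("kl.mode must be 'normalized' or 'raw'")
        if not (self.floor > 0):
            raise ConfigError("kl.floor must be positive")


@dataclass
class KineticConfig:
    nx: int = 64
    nxi: int = 32
    xi_max: float = 8.0
    L: float = 1.0
    tau: float = 0.1
    tol: float = 1e-8
    max_iter: int = 10_000

    def __post_init__(self):
        if self.nx < 2 or self.nxi < 2:
            raise ConfigError("kinetic.nx and kinetic.nxi must be >= 2")
        if self.nxi % 2:
            raise ConfigError("kinetic.nxi must be even")
        if not (self.xi_max > 0 and self.L > 0 and self.tau > 0 and self.tol > 0):
            raise ConfigError("kinetic scales and tolerance must be positive")
        if self.max_iter < 1:
            raise ConfigError("kinetic.max_iter must be >= 1")


@dataclass
class AllometryConfig:
    heartbeat: float = 0.1
    metabolic_time: float = 3.0
    beats_per_lifetime: float = 1e9
    lifetime_correction: float = 1.0

    def __post_init__(self):
        for f in fields(self):
            if not (getattr(self, f.name) > 0):
                raise ConfigError(f"allometry.{f.name} must be positive")


@dataclass
class RunConfig:
    """Top-level validated configuration for a CLI run."""

    seed: int = 0
    out_dir: str = "results"
    verbosity: int = 1
    kl: KLConfig = field(default_factory=KLConfig)
    kinetic: KineticConfig = field(default_factory=KineticConfig)
    simulation: AgingSimConfig = field(default_factory=AgingSimConfig)
    allometry: AllometryConfig = field(default_factory=AllometryConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "kl": KLConfig,
    "kinetic": KineticConfig,
    "simulation": AgingSimConfig,
    "allometry": AllometryConfig,
}
_SCALARS = {"seed": int, "out_dir": str, "verbosity": int}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{section}': {sorted(unknown)}"
        )
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{section}': {exc}") from exc


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a :class:`RunConfig` from YAML, with optional
    programmatic overrides (nested dict merged over the file contents)."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
        data = raw
    for key, sub in (overrides or {}).items():
        if isinstance(sub, dict):
            data.setdefault(key, {})
            if not isinstance(data[key], dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            data[key].update(sub)
        else:
            data[key] = sub

    unknown = set(data) - set(_SECTIONS) - set(_SCALARS)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    kwargs = {}
    for key, caster in _SCALARS.items():
        if key in data:
            kwargs[key] = caster(data[key])
    for key, cls in _SECTIONS.items():
        section = data.get(key, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section '{key}' must be a mapping")
        kwargs[key] = _build_section(cls, section, key)
    return RunConfig(**kwargs)
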