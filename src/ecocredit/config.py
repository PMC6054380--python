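"""Scenario configuration: dataclass schema plus YAML round-tripping.

A configuration has four sections — ``environment``, ``economy``,
``governance`` and ``simulation`` — mapping one-to-one onto the parameter
dataclasses of the corresponding modules.  Files are flat key-value YAML
under those four section headings; unknown keys and malformed values are
reported with their full field names.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .economy import EconomyParams
from .environment import EnvironmentParams
from .governance import Government

__all__ = ["SimulationParams", "SimulationConfig", "load_config", "save_config"]


@dataclass
class SimulationParams:
    horizon: int = 250
    collapse_epsilon: float = 0.01  # collapse when stock < epsilon * initial
    seed: int = 0
    record_processes: bool = False

    def validate(self) -> None:
        if self.horizon < 0:
            raise ValueError("simulation.horizon must be >= 0")
        if not 0.0 <= self.collapse_epsilon <= 1.0:
            raise ValueError("simulation.collapse_epsilon must be in [0, 1]")


@dataclass
class SimulationConfig:
    environment: EnvironmentParams = field(default_factory=EnvironmentParams)
    economy: EconomyParams = field(default_factory=EconomyParams)
    governance: Government = field(default_factory=Government)
    simulation: SimulationParams = field(default_factory=SimulationParams)

    def validate(self) -> "SimulationConfig":
        self.environment.validate()
        self.economy.validate()
        self.governance.validate()
        self.simulation.validate()
        return self

    # -- generic field access (used by the OFAT sweep) ----------------------
    def get(self, dotted: str):
        section, _, name = dotted.partition(".")
        if not name:
            raise KeyError(f"parameter name must be 'section.field', got {dotted!r}")
        try:
            holder = getattr(self, section)
            return getattr(holder, name)
        except AttributeError as exc:
            raise KeyError(f"unknown config parameter {dotted!r}") from exc

    def with_value(self, dotted: str, value) -> "SimulationConfig":
        section, _, name = dotted.partition(".")
        self.get(dotted)  # raises KeyError on unknown names
        holder = getattr(self, section)
        new_holder = replace(holder, **{name: value})
        return replace(self, **{section: new_holder})

    def copy(self) -> "SimulationConfig":
        return SimulationConfig(
            environment=replace(self.environment),
            economy=replace(self.economy),
            governance=replace(self.governance),
            simulation=replace(self.simulation),
        )

    def to_dict(self) -> dict:
        out = {}
        for section in ("environment", "economy", "governance", "simulation"):
            out[section] = dataclasses.asdict(getattr(self, section))
        return out


_SECTION_TYPES = {
    "environment": EnvironmentParams,
    "economy": EconomyParams,
    "governance": Government,
    "simulation": SimulationParams,
}


def _build_section(name: str, cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown field(s) in section '{name}': {', '.join(sorted(unknown))}"
        )
    try:
        return cls(**data)
    except TypeError as exc:
        raise ValueError(f"invalid section '{name}': {exc}") from exc


def config_from_dict(data: dict) -> SimulationConfig:
    unknown = set(data) - set(_SECTION_TYPES)
    if unknown:
        raise ValueError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        kwargs[section] = _build_section(section, cls, dict(data.get(section, {})))
    return SimulationConfig(**kwargs).validate()


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping of sections")
    return config_from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
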