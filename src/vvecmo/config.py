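"""Scenario configuration: defaults, validation, (de)serialisation.

A scenario is a flat key-value document (YAML).  Unspecified fields take
the standard defaults (FIO2 1.0, FoxyO2 1.0, QT 6 l/min, VO2 250 ml/min,
Hb 10 g/dl, DP50 0, temp 37 degC, RQ 0.8, VD 1.847 l/min, no circuit
shunt, no recirculation, no extracorporeal exchange); unknown keys are
rejected.  Units are fixed by the schema and encoded in the field names
of the result tables, not per entry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError, DomainError
from .scenarios import LungStrategy, SweepStrategy
from .solver import DEFAULT_TOL, ModelInputs

__all__ = ["ScenarioConfig", "load_config", "config_to_dict"]

_MODEL_FIELDS = {f.name for f in dataclasses.fields(ModelInputs)}


@dataclass(frozen=True)
class ScenarioConfig:
    """A validated scenario: model inputs + strategies + run settings."""

    inputs: ModelInputs = field(default_factory=ModelInputs)
    lung_strategy: LungStrategy = field(default_factory=LungStrategy)
    sweep_strategy: SweepStrategy | None = None
    grid_axes: dict = field(default_factory=dict)
    out_path: str | None = None
    tol_mmhg: float = DEFAULT_TOL

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.inputs)
        d["lung_strategy"] = self.lung_strategy.kind
        if self.sweep_strategy is not None:
            d["sweep_strategy"] = dataclasses.asdict(self.sweep_strategy)
        if self.grid_axes:
            d["grid_axes"] = {k: list(v) for k, v in self.grid_axes.items()}
        if self.out_path:
            d["out_path"] = self.out_path
        d["tol_mmhg"] = self.tol_mmhg
        return d


def _build_inputs(data: dict) -> ModelInputs:
    if "ve" in data and "va" not in data:
        data["va"] = None  # VE given: derive VA through VD
    try:
        return ModelInputs(**data)
    except DomainError as exc:
        raise ConfigError(str(exc)) from exc
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def config_from_dict(data: dict) -> ScenarioConfig:
    data = dict(data or {})
    lung_kind = data.pop("lung_strategy", "standard_ards")
    sweep_raw = data.pop("sweep_strategy", None)
    grid_axes = data.pop("grid_axes", {}) or {}
    out_path = data.pop("out_path", None)
    tol = data.pop("tol_mmhg", DEFAULT_TOL)

    unknown = set(data) - _MODEL_FIELDS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    data = {k: v for k, v in data.items() if v is not None}
    for k, v in data.items():
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ConfigError(f"field {k!r} must be numeric, got {v!r}")
    inputs = _build_inputs(data)

    try:
        lung = LungStrategy(kind=lung_kind)
    except DomainError as exc:
        raise ConfigError(str(exc)) from exc
    sweep = None
    if sweep_raw is not None:
        if isinstance(sweep_raw, str):
            sweep_raw = {"kind": sweep_raw}
        try:
            sweep = SweepStrategy(**sweep_raw)
        except (DomainError, TypeError) as exc:
            raise ConfigError(str(exc)) from exc

    bad_axes = set(grid_axes) - _MODEL_FIELDS
    if bad_axes:
        raise ConfigError(f"grid axes over unknown fields: {sorted(bad_axes)}")
    if not (0 < tol <= 1.0):
        raise ConfigError("tol_mmhg must be in (0, 1]")
    return ScenarioConfig(inputs=inputs, lung_strategy=lung,
                          sweep_strategy=sweep, grid_axes=grid_axes,
                          out_path=out_path, tol_mmhg=float(tol))


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> ScenarioConfig:
    """Load a scenario from a YAML file, applying ``overrides`` on top.

    An absent/empty file yields the full default scenario.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path} must contain a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    return config_from_dict(data)


def config_to_dict(cfg: ScenarioConfig) -> dict:
    return cfg.to_dict()
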