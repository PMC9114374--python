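"""Run configuration and flat key-value (YAML) serialization.

The config file is a flat mapping with dotted keys for nested parameter
groups, e.g.::

    nu: 150
    nv: 150
    centers: [[75.0, 75.0]]
    params.m_phi: 60.0
    params.anisotropy.delta_aniso: 0.1
    params.schedule.iters_stage1: 200
    solver.newton_tol: 1.0e-4

Every :class:`~neurongrowth.growth_model.ModelParameters`,
:class:`~neurongrowth.time_integrator.SolverSettings` and schedule field is
addressable; unspecified keys keep their documented defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError
from .growth_model import (
    AnisotropyParams,
    CueParams,
    ModelParameters,
    RateParams,
    StageSchedule,
    TemperatureParams,
    TubulinParams,
)
from .time_integrator import SolverSettings

__all__ = ["RunConfig", "load_config", "save_config", "config_to_flat_dict",
           "config_from_flat_dict"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one growth run."""
    nu: int = 150
    nv: int = 150
    centers: list = field(default_factory=lambda: [[75.0, 75.0]])
    params: ModelParameters = field(default_factory=ModelParameters)
    solver: SolverSettings = field(default_factory=SolverSettings)
    name: str = "run"
    retip_every: int = 25
    snapshot_every: int = 500
    cue_every: int = 250       # re-sample each tip's guidance cue this often
    tip_min_separation: float = 8.0
    heading_window: int = 10
    match_radius: float = 6.0
    extension_margin: int = 10
    extension_width: int = 10
    extend_all_directions: bool = False
    max_extensions: int = 20
    guard_enabled: bool = True
    guard_window: int = 5


_NESTED_PARAM_TYPES = {
    "anisotropy": AnisotropyParams,
    "tubulin": TubulinParams,
    "rates": RateParams,
    "cue": CueParams,
    "temperature": TemperatureParams,
    "schedule": StageSchedule,
}


def _flatten(prefix: str, obj, out: dict):
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        key = f"{prefix}{f.name}"
        if dataclasses.is_dataclass(v):
            _flatten(key + ".", v, out)
        elif isinstance(v, tuple):
            out[key] = list(v)
        else:
            out[key] = v


def config_to_flat_dict(config: RunConfig) -> dict:
    out: dict = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if f.name == "params":
            _flatten("params.", v, out)
        elif f.name == "solver":
            _flatten("solver.", v, out)
        else:
            out[f.name] = v
    return out


def config_from_flat_dict(flat: dict) -> RunConfig:
    params_kw: dict = {}
    nested_kw: dict[str, dict] = {k: {} for k in _NESTED_PARAM_TYPES}
    solver_kw: dict = {}
    top_kw: dict = {}
    top_names = {f.name for f in dataclasses.fields(RunConfig)}
    param_names = {f.name for f in dataclasses.fields(ModelParameters)}
    solver_names = {f.name for f in dataclasses.fields(SolverSettings)}
    for key, v in flat.items():
        parts = key.split(".")
        if parts[0] == "params":
            if len(parts) == 3 and parts[1] in nested_kw:
                nested_kw[parts[1]][parts[2]] = v
            elif len(parts) == 2 and parts[1] in param_names:
                params_kw[parts[1]] = tuple(v) if isinstance(v, list) else v
            else:
                raise ConfigurationError(f"unknown config key: {key}")
        elif parts[0] == "solver" and len(parts) == 2 \
                and parts[1] in solver_names:
            solver_kw[parts[1]] = v
        elif key in top_names:
            top_kw[key] = v
        else:
            raise ConfigurationError(f"unknown config key: {key}")
    for group, cls in _NESTED_PARAM_TYPES.items():
        if nested_kw[group]:
            kw = {k: tuple(v) if isinstance(v, list) else v
                  for k, v in nested_kw[group].items()}
            params_kw[group] = cls(**kw)
    params = ModelParameters(**params_kw)
    solver = SolverSettings(**solver_kw)
    return RunConfig(params=params, solver=solver, **top_kw)


def save_config(config: RunConfig, path) -> None:
    """Write the flat key-value config to a YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_flat_dict(config), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    """Load a flat key-value YAML config."""
    with open(path) as fh:
        flat = yaml.safe_load(fh) or {}
    if not isinstance(flat, dict):
        raise ConfigurationError("config file must be a flat mapping")
    return config_from_flat_dict(flat)
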