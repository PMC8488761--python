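"""Run configuration: a validated YAML schema for one-command reproduction.

A run config names a model ('i', 'ii' or 'iii'), a mode ('trajectory',
'sweep', 'equilibria' or 'invade'), the model's parameters and the numerical
settings of the run.  Unknown keys and parameters that do not belong to the
chosen model are rejected with field-level messages.  The dynamics are
deterministic mean-field recursions, so the schema deliberately has no seed
field — identical configs always reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Optional

import yaml

from .experiments import AxisSpec, DEFAULT_SWEEP_HORIZON
from .invasion import DEFAULT_EPSILON, DEFAULT_HORIZON, ORIGINS
from .models import PARAM_TYPES, ModelParams

__all__ = ["RunConfig", "ConfigError", "parse_config", "builtin_config_path"]

SCHEMA_VERSION = 1

MODES = ("trajectory", "sweep", "equilibria", "invade")

_TOP_KEYS = {
    "schema",
    "model",
    "mode",
    "params",
    "origin",
    "epsilon",
    "horizon",
    "tol",
    "output",
    "grid",
    "h_list",
}
_GRID_KEYS = {"axis1", "axis2"}
_AXIS_KEYS = {"name", "lo", "hi", "n"}


class ConfigError(ValueError):
    """A configuration file violated the schema."""


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one run."""

    model: str
    mode: str
    params: ModelParams
    origin: Optional[str] = None
    epsilon: float = DEFAULT_EPSILON
    horizon: int = DEFAULT_HORIZON
    tol: float = 1e-12
    output: Optional[str] = None
    grid: Optional[tuple[AxisSpec, AxisSpec]] = None
    h_list: Optional[tuple[float, ...]] = None  #: CI sweep panels (model iii)

    def resolved(self) -> dict:
        """Plain-dict echo of every resolved field (for logging)."""
        out = {}
        for f in dc_fields(self):
            out[f.name] = getattr(self, f.name)
        return out


def _axis(raw, which: str) -> AxisSpec:
    if not isinstance(raw, dict):
        raise ConfigError(f"grid.{which} must be a mapping with keys {_AXIS_KEYS}")
    unknown = set(raw) - _AXIS_KEYS
    if unknown:
        raise ConfigError(f"grid.{which}: unknown keys {sorted(unknown)}")
    missing = _AXIS_KEYS - set(raw)
    if missing:
        raise ConfigError(f"grid.{which}: missing keys {sorted(missing)}")
    try:
        spec = AxisSpec(str(raw["name"]), float(raw["lo"]), float(raw["hi"]),
                        int(raw["n"]))
    except (TypeError, ValueError) as err:
        raise ConfigError(f"grid.{which}: {err}") from err
    if spec.n < 1:
        raise ConfigError(f"grid.{which}.n must be >= 1, got {spec.n}")
    return spec


def parse_config(source) -> RunConfig:
    """Parse and validate a config from a YAML file path or a dict.

    Every default is filled in so :meth:`RunConfig.resolved` echoes the full
    effective configuration.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    schema = raw.get("schema", SCHEMA_VERSION)
    if schema != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema version {schema!r}")

    model = raw.get("model")
    if model not in PARAM_TYPES:
        raise ConfigError(f"model must be one of {sorted(PARAM_TYPES)}, got {model!r}")
    mode = raw.get("mode")
    if mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}, got {mode!r}")

    params_raw = raw.get("params")
    if not isinstance(params_raw, dict):
        raise ConfigError("params must be a mapping of parameter values")
    ptype = PARAM_TYPES[model]
    allowed = {f.name for f in dc_fields(ptype)}
    bad = set(params_raw) - allowed
    if bad:
        raise ConfigError(
            f"params {sorted(bad)} do not belong to model {model} "
            f"(allowed: {sorted(allowed)})"
        )
    try:
        params = ptype(**{k: float(v) for k, v in params_raw.items()})
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid params for model {model}: {err}") from err

    origin = raw.get("origin")
    if mode in ("trajectory", "sweep", "invade"):
        if origin not in ORIGINS:
            raise ConfigError(
                f"mode {mode!r} requires origin in {ORIGINS}, got {origin!r}"
            )
    elif origin is not None and origin not in ORIGINS:
        raise ConfigError(f"origin must be one of {ORIGINS}, got {origin!r}")

    grid = None
    if mode == "sweep":
        graw = raw.get("grid")
        if not isinstance(graw, dict):
            raise ConfigError("sweep mode requires a grid mapping")
        unknown = set(graw) - _GRID_KEYS
        if unknown:
            raise ConfigError(f"grid: unknown keys {sorted(unknown)}")
        if _GRID_KEYS - set(graw):
            raise ConfigError("grid requires both axis1 and axis2")
        grid = (_axis(graw["axis1"], "axis1"), _axis(graw["axis2"], "axis2"))
        for ax in grid:
            if ax.name not in allowed:
                raise ConfigError(
                    f"grid axis {ax.name!r} is not a parameter of model {model}"
                )
    elif "grid" in raw:
        raise ConfigError(f"grid is only valid in sweep mode, not {mode!r}")

    h_list = None
    if "h_list" in raw:
        if model != "iii" or mode != "sweep":
            raise ConfigError("h_list is only valid for model iii sweeps")
        try:
            h_list = tuple(float(h) for h in raw["h_list"])
        except (TypeError, ValueError) as err:
            raise ConfigError(f"h_list must be a list of numbers: {err}") from err

    try:
        epsilon = float(raw.get("epsilon", DEFAULT_EPSILON))
        default_h = DEFAULT_SWEEP_HORIZON if mode == "sweep" else DEFAULT_HORIZON
        horizon = int(raw.get("horizon", default_h))
        tol = float(raw.get("tol", 1e-12))
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid numeric setting: {err}") from err
    if not 0.0 <= epsilon < 1.0:
        raise ConfigError(f"epsilon must be in [0, 1), got {epsilon}")
    if horizon < 1:
        raise ConfigError(f"horizon must be >= 1, got {horizon}")
    if not tol > 0:
        raise ConfigError(f"tol must be positive, got {tol}")

    output = raw.get("output")
    if output is not None:
        output = str(output)

    return RunConfig(
        model=model,
        mode=mode,
        params=params,
        origin=origin,
        epsilon=epsilon,
        horizon=horizon,
        tol=tol,
        output=output,
        grid=grid,
        h_list=h_list,
    )


def builtin_config_path(name: str) -> Path:
    """Path of a config shipped with the package (e.g. ``'fig1'``)."""
    here = Path(__file__).parent / "configs"
    path = here / f"{name}.yaml"
    if not path.exists():
        available = sorted(p.stem for p in here.glob("*.yaml"))
        raise ConfigError(f"no built-in config {name!r}; available: {available}")
    return path
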