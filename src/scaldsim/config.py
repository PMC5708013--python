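"""YAML configuration: defaults, loading, validation and object building.

Every physical constant of the model is exposed here; an empty config file
reproduces the base scenario (85 degC spill on 1.0 mm fabric over a 50 um
epidermis, fabric never removed).  Unknown keys are rejected so typos fail
loudly.  SI units throughout; temperatures in degC.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

from .damage import DamageParams
from .materials import (
    BloodModel,
    InvalidParameterError,
    LayerStack,
    SkinLayer,
    WetFabricSpec,
)
from .solver import ExposureTimeline, SolverConfig

__all__ = ["default_config", "load_config", "build_objects", "ConfigError"]


class ConfigError(ValueError):
    """Malformed configuration file."""


#: Full default configuration (the base scenario).
_DEFAULTS: dict[str, Any] = {
    "layers": [
        {"name": "epidermis", "k": 0.22, "rho": 1200.0, "C": 3600.0, "thickness": 50e-6},
        {"name": "dermis", "k": 0.40, "rho": 1200.0, "C": 3600.0, "thickness": 0.002},
        {"name": "subcutaneous", "k": 0.20, "rho": 1000.0, "C": 2500.0, "thickness": 0.010},
        {"name": "muscle", "k": 0.45, "rho": 1000.0, "C": 3800.0, "thickness": 0.030},
    ],
    "fabric": {
        "present": True,
        "thickness": 1.0e-3,
        "T_spill": 85.0,
        "T_dry": 30.0,
        "k_wet": 0.65,
        "rhoC_wet": 3.6e6,
    },
    "timeline": {
        "t_end": 30.0,
        "t_off": None,
        "t_cool": None,
        "T_air": 20.0,
        "T_water_cool": 20.0,
        "h_air": 10.0,
        "h_water": 600.0,
    },
    "solver": {
        "dt": 2e-4,
        "dx": 10e-6,
        "Q_ext": 0.0,
        "record_interval": 0.01,
        "field_interval": 0.05,
    },
    "blood": {
        "enabled": True,
        "Wb": 1.25e-3,
        "rho_b": 1060.0,
        "C_b": 3770.0,
        "T_b": 37.0,
        "Q_met": 420.0,
        "perfused_layers": ["dermis", "subcutaneous", "muscle"],
    },
    "damage": {
        "P": 3.1e98,
        "dE": 6.28e5,
        "R": 8.314,
        "T_threshold": 43.0,
        "quadrature": "trapezoid",
    },
}


def default_config() -> dict[str, Any]:
    """A deep copy of the full default configuration."""
    return copy.deepcopy(_DEFAULTS)


def _merge(defaults: dict[str, Any], user: dict[str, Any], path: str) -> dict[str, Any]:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key {path + key!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{path + key!r} must be a mapping")
            out[key] = _merge(defaults[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config file, applying defaults for every omitted key.

    ``path=None`` or an empty file yields the full default configuration.
    """
    if path is None:
        return default_config()
    text = Path(path).read_text()
    try:
        user = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if user is None:
        return default_config()
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return _merge(_DEFAULTS, user, "")


def build_objects(
    cfg: dict[str, Any],
) -> tuple[LayerStack, WetFabricSpec | None, ExposureTimeline, SolverConfig, DamageParams]:
    """Turn a (merged) configuration into the model objects.

    Raises :class:`ConfigError` for physically inadmissible values,
    including a time step violating the Fourier stability bound.
    """
    try:
        stack = LayerStack(
            tuple(
                SkinLayer(d["name"], d["k"], d["rho"], d["C"], d["thickness"])
                for d in cfg["layers"]
            )
        )
        f = cfg["fabric"]
        fabric = (
            WetFabricSpec(
                thickness=f["thickness"],
                T_spill=f["T_spill"],
                T_dry=f["T_dry"],
                k_wet=f["k_wet"],
                rhoC_wet=f["rhoC_wet"],
            )
            if f["present"]
            else None
        )
        timeline = ExposureTimeline(**cfg["timeline"])
        b = cfg["blood"]
        blood = BloodModel(
            Wb=b["Wb"],
            rho_b=b["rho_b"],
            C_b=b["C_b"],
            T_b=b["T_b"],
            Q_met=b["Q_met"],
            perfused_layers=tuple(b["perfused_layers"]),
            enabled=b["enabled"],
        )
        solver = SolverConfig(blood=blood, **cfg["solver"])
        damage = DamageParams(**cfg["damage"])
    except (InvalidParameterError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc

    # fail before any stepping if the explicit scheme would be unstable
    from .solver import Grid1D, _require_stable

    try:
        grid = Grid1D.from_layers(stack, fabric, solver.dx)
        _require_stable(grid, solver.dt)
    except (InvalidParameterError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return stack, fabric, timeline, solver, damage
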