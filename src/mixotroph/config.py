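"""Run configuration, validation and reproducible run execution.

A run is described by a small YAML mapping::

    scenario: scan            # budget | curves | scan | season | depthseason
    params:                   # optional parameter-table overrides
      r_0: 0.06
    settings:                 # scenario-specific knobs (see _SETTING_KEYS)
      axis: food
      min: 1.0
      max: 10000.0
      n: 30
      log_spacing: true
    output: runs/prey_scan
    seed: 0

Unknown keys anywhere are rejected.  Each run writes its result tables
(CSV), a plain-text log (parameters, provenance notes, versions, seed) and
a ``manifest.json`` carrying the fully resolved configuration, so a rerun
from the manifest reproduces the tables byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ALPHA_L_NOTE, Environment, ModelParams, TraitSet, budget_frame, compute_budget
from .optimize import SCAN_AXES, gradient_scan
from .scenarios import (
    DEFAULT_PRESETS,
    DepthSeasonConfig,
    SeasonalForcingConfig,
    depth_season_forcing,
    growth_vs_light_curve,
    ingestion_vs_light_curve,
    seasonal_surface_forcing,
    succession_run,
)

__all__ = ["RunConfig", "ConfigError", "load_run_config", "run"]

logger = logging.getLogger("mixotroph")

SCENARIOS = ("budget", "curves", "scan", "season", "depthseason")

_FORCING_KEYS = tuple(f for f in SeasonalForcingConfig.__dataclass_fields__)
_DEPTH_KEYS = tuple(f for f in DepthSeasonConfig.__dataclass_fields__ if f != "surface")

_SETTING_KEYS: dict[str, tuple[str, ...]] = {
    "budget": ("preset", "phi_L", "phi_F", "phi_N", "X_L", "X_N", "X_F"),
    "curves": ("kind", "preset", "light_min", "light_max", "n_light",
               "log_spacing", "fed", "food", "nutrients"),
    "scan": ("axis", "min", "max", "n", "log_spacing",
             "X_L", "X_N", "X_F", "tolerance"),
    "season": ("tolerance",) + _FORCING_KEYS,
    "depthseason": ("tolerance",) + _FORCING_KEYS + _DEPTH_KEYS,
}

_CSV_FLOAT_FORMAT = "%.12g"


class ConfigError(ValueError):
    """An invalid run configuration (unknown key, bad value, missing field)."""


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one reproducible run."""

    scenario: str
    params: dict[str, float] = field(default_factory=dict)
    settings: dict[str, Any] = field(default_factory=dict)
    output: str = "mixotroph_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        unknown = sorted(set(self.params) - set(ModelParams.field_names()))
        if unknown:
            raise ConfigError(f"unknown parameter key(s): {', '.join(unknown)}")
        allowed = _SETTING_KEYS[self.scenario]
        unknown = sorted(set(self.settings) - set(allowed))
        if unknown:
            raise ConfigError(
                f"unknown setting key(s) for scenario {self.scenario!r}: {', '.join(unknown)}"
            )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping")
    return run_config_from_mapping(raw)


def run_config_from_mapping(raw: Mapping[str, Any]) -> RunConfig:
    allowed = {"scenario", "params", "settings", "output", "seed"}
    unknown = sorted(set(raw) - allowed)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    if "scenario" not in raw:
        raise ConfigError("config is missing the required 'scenario' key")
    return RunConfig(
        scenario=str(raw["scenario"]),
        params=dict(raw.get("params") or {}),
        settings=dict(raw.get("settings") or {}),
        output=str(raw.get("output", "mixotroph_run")),
        seed=int(raw.get("seed", 0)),
    )


def _resolve_preset(settings: Mapping[str, Any]) -> TraitSet:
    if "preset" in settings:
        label = str(settings["preset"])
        for preset in DEFAULT_PRESETS:
            if preset.label.lower().replace(".", "").replace(" ", "") == \
                    label.lower().replace(".", "").replace(" ", ""):
                return preset.traits
        raise ConfigError(
            f"unknown preset {label!r}; available: "
            + ", ".join(p.label for p in DEFAULT_PRESETS)
        )
    try:
        return TraitSet(float(settings.get("phi_L", 0.0)),
                        float(settings.get("phi_F", 0.0)),
                        float(settings.get("phi_N", 0.0)))
    except ValueError as exc:
        raise ConfigError(f"infeasible trait input: {exc}") from exc


def _light_axis(settings: Mapping[str, Any]) -> np.ndarray:
    lo = float(settings.get("light_min", 1.0))
    hi = float(settings.get("light_max", 400.0))
    n = int(settings.get("n_light", 30))
    if settings.get("log_spacing", False):
        return np.logspace(np.log10(lo), np.log10(hi), n)
    return np.linspace(lo, hi, n)


def _run_budget(cfg: RunConfig, params: ModelParams, outdir: Path) -> list[Path]:
    traits = _resolve_preset(cfg.settings)
    env = Environment(float(cfg.settings.get("X_L", 100.0)),
                      float(cfg.settings.get("X_N", 10.0)),
                      float(cfg.settings.get("X_F", 10.0)))
    budget = compute_budget(traits, env, params)
    table = budget_frame([(traits, env, budget)])
    path = outdir / "budget.csv"
    table.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)
    return [path]


def _run_curves(cfg: RunConfig, params: ModelParams, outdir: Path) -> list[Path]:
    from .scenarios import SpeciesPreset

    kind = str(cfg.settings.get("kind", "growth"))
    if kind not in ("ingestion", "growth"):
        raise ConfigError(f"curves kind must be 'ingestion' or 'growth', got {kind!r}")
    traits = _resolve_preset(cfg.settings)
    preset = SpeciesPreset(str(cfg.settings.get("preset", "custom")), traits)
    light = _light_axis(cfg.settings)
    kwargs: dict[str, float] = {}
    if "food" in cfg.settings:
        kwargs["food"] = float(cfg.settings["food"])
    if "nutrients" in cfg.settings:
        kwargs["nutrients"] = float(cfg.settings["nutrients"])
    if kind == "ingestion":
        table = ingestion_vs_light_curve(preset, light, params, **kwargs)
    else:
        table = growth_vs_light_curve(preset, light, bool(cfg.settings.get("fed", False)),
                                      params, **kwargs)
    path = outdir / f"{kind}_curve.csv"
    table.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)
    return [path]


def _run_scan(cfg: RunConfig, params: ModelParams, outdir: Path) -> list[Path]:
    axis = str(cfg.settings.get("axis", "food"))
    if axis not in SCAN_AXES:
        raise ConfigError(f"scan axis must be one of {sorted(SCAN_AXES)}, got {axis!r}")
    lo = float(cfg.settings.get("min", 1.0))
    hi = float(cfg.settings.get("max", 1e4))
    n = int(cfg.settings.get("n", 30))
    values = (np.logspace(np.log10(lo), np.log10(hi), n)
              if cfg.settings.get("log_spacing", True) else np.linspace(lo, hi, n))
    base = Environment(float(cfg.settings.get("X_L", 200.0)),
                       float(cfg.settings.get("X_N", 1.0)),
                       float(cfg.settings.get("X_F", 5.0)))
    table = gradient_scan(axis, values, base, params,
                          tolerance=float(cfg.settings.get("tolerance", 0.95)))
    path = outdir / "scan.csv"
    table.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)
    return [path]


def _forcing_config(settings: Mapping[str, Any]) -> SeasonalForcingConfig:
    kwargs = {k: settings[k] for k in _FORCING_KEYS if k in settings}
    if "n_time" in kwargs:
        kwargs["n_time"] = int(kwargs["n_time"])
    return SeasonalForcingConfig(**kwargs)


def _run_season(cfg: RunConfig, params: ModelParams, outdir: Path) -> list[Path]:
    forcing = seasonal_surface_forcing(_forcing_config(cfg.settings))
    table = succession_run(forcing, params,
                           tolerance=float(cfg.settings.get("tolerance", 0.95)))
    paths = [outdir / "season.csv", outdir / "forcing.csv"]
    table.to_csv(paths[0], index=False, float_format=_CSV_FLOAT_FORMAT)
    forcing.to_frame().to_csv(paths[1], index=False, float_format=_CSV_FLOAT_FORMAT)
    return paths


def _run_depthseason(cfg: RunConfig, params: ModelParams, outdir: Path) -> list[Path]:
    surface = _forcing_config(cfg.settings)
    kwargs = {k: cfg.settings[k] for k in _DEPTH_KEYS if k in cfg.settings}
    if "n_depth" in kwargs:
        kwargs["n_depth"] = int(kwargs["n_depth"])
    forcing = depth_season_forcing(DepthSeasonConfig(surface=surface, **kwargs))
    table = succession_run(forcing, params,
                           tolerance=float(cfg.settings.get("tolerance", 0.95)))
    paths = [outdir / "depthseason.csv", outdir / "forcing.csv"]
    table.to_csv(paths[0], index=False, float_format=_CSV_FLOAT_FORMAT)
    forcing.to_frame().to_csv(paths[1], index=False, float_format=_CSV_FLOAT_FORMAT)
    return paths


_RUNNERS = {
    "budget": _run_budget,
    "curves": _run_curves,
    "scan": _run_scan,
    "season": _run_season,
    "depthseason": _run_depthseason,
}


def run(config: RunConfig) -> list[Path]:
    """Execute a run: result tables + log + manifest in the output directory.

    Identical configuration (including seed) reproduces the result tables
    byte for byte.  Returns the paths of the written result tables.
    """
    try:
        params = ModelParams.from_mapping(config.params) if config.params else ModelParams()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    outdir = Path(config.output)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("mixotroph %s scenario=%s seed=%d", __version__, config.scenario, config.seed)
    if "alpha_L" not in config.params:
        logger.info("%s", ALPHA_L_NOTE)

    tables = _RUNNERS[config.scenario](config, params, outdir)

    log_lines = [
        f"mixotroph version: {__version__}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"scenario: {config.scenario}",
        f"seed: {config.seed}",
        "parameters:",
    ]
    log_lines += [f"  {k} = {v!r}" for k, v in params.to_dict().items()]
    if "alpha_L" not in config.params:
        log_lines.append(f"note: {ALPHA_L_NOTE}")
    log_lines.append("tables: " + ", ".join(p.name for p in tables))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "parameters": params.to_dict(),
        "tables": [p.name for p in tables],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return tables
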