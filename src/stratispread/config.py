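"""Declarative model-definition files.

A simulation is described in a YAML file whose keys mirror the
simulation types.  The schema is validated strictly: unknown keys are
rejected, and every defaulted value is echoed to the log so a run's full
parameterisation is always on record.  Carrying capacity and survival
accept either a scalar or ``{raster: path}`` pointing at an Esri ASCII
grid.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .dispersal import KernelComponent, KernelSpec, LocalDispersalSpec
from .engine import SimulationConfig
from .growth import GrowthSpec
from .raster import read_ascii_grid
from .survival import SurvivalSpec

__all__ = ["ConfigError", "load_config", "config_to_dict", "save_config"]

log = logging.getLogger("stratispread")


class ConfigError(ValueError):
    """Raised when a model-definition file is invalid."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class _RasterRef(_Strict):
    raster: str


class _GrowthModel(_Strict):
    family: Literal["logistic", "beverton_holt", "ricker", "allee_logistic"] = "logistic"
    r: float = 0.5
    K: Union[float, _RasterRef] = 100.0
    A: float | None = None
    stochastic: bool = False


class _LocalModel(_Strict):
    proportion: float = 0.2
    shape: list[Literal["E", "N", "W", "S"]] = ["E", "N", "W", "S"]
    range: int = 1
    allocation: Literal["deterministic", "multinomial"] = "deterministic"


class _KernelComponentModel(_Strict):
    weight: float = 1.0
    family: Literal["cauchy", "exponential"] = "cauchy"
    x0: float = 0.0
    scale: float = 1.0


class _KernelModel(_Strict):
    lambda_events: float = 1.0
    components: list[_KernelComponentModel] = Field(
        default_factory=lambda: [_KernelComponentModel()]
    )
    propagule_size: float = 1.0


class _SurvivalModel(_Strict):
    s: Union[float, _RasterRef] = 1.0
    scope: Literal["all", "new_only"] = "all"


class _SimulationModel(_Strict):
    rows: int
    cols: int
    steps: int
    mode: Literal["abundance", "presence"] = "abundance"
    replicates: int = 1
    base_seed: int = 0
    initial: list[list[float]] = Field(default_factory=lambda: [[0, 0, 1.0]])
    cell_size: float = 1.0
    occupancy_threshold: float = 1.0
    order: list[Literal["growth", "local", "kernel", "survival"]] = [
        "growth", "local", "kernel", "survival"
    ]
    ros_first_time_only: bool = False
    density_over: Literal["occupied", "all"] = "occupied"
    snapshots_every: int | None = None
    growth: _GrowthModel | None = None
    local: _LocalModel | None = None
    kernel: _KernelModel | None = None
    survival: _SurvivalModel | None = None


def _resolve(value, base_dir: Path):
    if isinstance(value, _RasterRef):
        path = Path(value.raster)
        if not path.is_absolute():
            path = base_dir / path
        return read_ascii_grid(path).values
    return value


def load_config(path) -> SimulationConfig:
    """Parse and validate a model-definition YAML file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        model = _SimulationModel.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc

    defaulted = sorted(set(_SimulationModel.model_fields) - set(raw))
    if defaulted:
        log.info("config %s: defaults used for %s", path.name, ", ".join(defaulted))

    base = path.parent
    growth = local = kernel = survival = None
    if model.growth is not None:
        growth = GrowthSpec(
            family=model.growth.family, r=model.growth.r,
            K=_resolve(model.growth.K, base), A=model.growth.A,
            stochastic=model.growth.stochastic,
        )
    if model.local is not None:
        local = LocalDispersalSpec(
            proportion=model.local.proportion, shape=tuple(model.local.shape),
            range=model.local.range, allocation=model.local.allocation,
        )
    if model.kernel is not None:
        kernel = KernelSpec(
            lambda_events=model.kernel.lambda_events,
            components=tuple(
                KernelComponent(weight=c.weight, family=c.family, x0=c.x0,
                                scale=c.scale)
                for c in model.kernel.components
            ),
            propagule_size=model.kernel.propagule_size,
        )
    if model.survival is not None:
        survival = SurvivalSpec(s=_resolve(model.survival.s, base),
                                scope=model.survival.scope)

    initial = []
    for cell in model.initial:
        if len(cell) == 2:
            r, c = cell
            n = 1.0
        elif len(cell) == 3:
            r, c, n = cell
        else:
            raise ConfigError(f"{path}: initial cells must be [row, col] or "
                              f"[row, col, abundance], got {cell}")
        initial.append((int(r), int(c), float(n)))

    try:
        cfg = SimulationConfig(
            rows=model.rows, cols=model.cols, steps=model.steps, mode=model.mode,
            replicates=model.replicates, base_seed=model.base_seed,
            initial=tuple(initial), cell_size=model.cell_size,
            growth=growth, local=local, kernel=kernel, survival=survival,
            occupancy_threshold=model.occupancy_threshold,
            order=tuple(model.order),
            ros_first_time_only=model.ros_first_time_only,
            density_over=model.density_over,
            snapshots_every=model.snapshots_every,
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    log.info("loaded config %s: %dx%d grid, %d steps, %d replicate(s), seed %d",
             path.name, cfg.rows, cfg.cols, cfg.steps, cfg.replicates, cfg.base_seed)
    return cfg


def config_to_dict(cfg: SimulationConfig) -> dict:
    """Serialize a SimulationConfig back to the YAML dialect (arrays for
    K/s are not representable and raise)."""
    out: dict = {
        "rows": cfg.rows, "cols": cfg.cols, "steps": cfg.steps, "mode": cfg.mode,
        "replicates": cfg.replicates, "base_seed": cfg.base_seed,
        "initial": [[r, c, n] for r, c, n in cfg.initial],
        "cell_size": cfg.cell_size,
        "occupancy_threshold": cfg.occupancy_threshold,
        "order": list(cfg.order),
        "ros_first_time_only": cfg.ros_first_time_only,
        "density_over": cfg.density_over,
    }
    if cfg.snapshots_every is not None:
        out["snapshots_every"] = cfg.snapshots_every
    if cfg.growth is not None:
        if isinstance(cfg.growth.K, np.ndarray):
            raise ConfigError("cannot serialize a per-cell K raster inline")
        out["growth"] = {"family": cfg.growth.family, "r": cfg.growth.r,
                         "K": cfg.growth.K, "stochastic": cfg.growth.stochastic}
        if cfg.growth.A is not None:
            out["growth"]["A"] = cfg.growth.A
    if cfg.local is not None:
        out["local"] = {"proportion": cfg.local.proportion,
                        "shape": list(cfg.local.shape), "range": cfg.local.range,
                        "allocation": cfg.local.allocation}
    if cfg.kernel is not None:
        out["kernel"] = {
            "lambda_events": cfg.kernel.lambda_events,
            "propagule_size": cfg.kernel.propagule_size,
            "components": [
                {"weight": c.weight, "family": c.family, "x0": c.x0,
                 "scale": c.scale}
                for c in cfg.kernel.components
            ],
        }
    if cfg.survival is not None:
        if isinstance(cfg.survival.s, np.ndarray):
            raise ConfigError("cannot serialize a survival raster inline")
        out["survival"] = {"s": cfg.survival.s, "scope": cfg.survival.scope}
    return out


def save_config(cfg: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
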