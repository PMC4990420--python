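"""Run configuration: flat key-value files with dotted namespaces.

A run is fully described by a :class:`RunConfig`; every output
directory receives a manifest serializing the complete effective
configuration (including defaults), which suffices to reproduce the
run exactly.

Config files are flat ``key = value`` text (also parseable as YAML),
with dotted namespaces selecting the component::

    model.gNaP = 2.5
    model.gCAN = 1.0
    solver.rtol = 1e-8
    metrics.split_s = 1.2
    grid.gnap = 0:3:0.25
    seed = 7

Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict

import numpy as np

from .burst_metrics import MetricsConfig
from .model_core import InvalidParameterError, ModelParameters
from .simulator import SolverSettings

__all__ = ["RunConfig", "load_config", "save_manifest", "parse_grid"]


class ConfigError(ValueError):
    """Malformed or unknown configuration."""


@dataclass
class RunConfig:
    model: ModelParameters = field(default_factory=ModelParameters)
    solver: SolverSettings = field(default_factory=SolverSettings)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    duration_s: float = 46.0
    i_app_pa: float = 0.0
    seed: int = 0
    gnap_grid: str = "0:3:0.25"
    gcan_grid: str = "0:4.5:0.25"

    def to_flat(self) -> Dict[str, Any]:
        flat: Dict[str, Any] = {}
        for ns, obj in (("model", self.model), ("solver", self.solver),
                        ("metrics", self.metrics)):
            for f in dataclasses.fields(obj):
                flat[f"{ns}.{f.name}"] = getattr(obj, f.name)
        flat["run.duration_s"] = self.duration_s
        flat["run.i_app_pa"] = self.i_app_pa
        flat["run.seed"] = self.seed
        flat["grid.gnap"] = self.gnap_grid
        flat["grid.gcan"] = self.gcan_grid
        return flat


def parse_grid(spec: str) -> np.ndarray:
    """Parse ``start:stop:step`` (inclusive stop) into a value grid."""
    try:
        start, stop, step = (float(x) for x in spec.split(":"))
    except ValueError as e:
        raise ConfigError(f"bad grid spec {spec!r}; use start:stop:step") from e
    if step <= 0 or stop < start:
        raise ConfigError(f"bad grid spec {spec!r}")
    return np.arange(start, stop + 1e-9, step)


def _coerce(value: str, target_type: type) -> Any:
    if target_type is bool:
        if value.lower() in ("true", "1", "yes"):
            return True
        if value.lower() in ("false", "0", "no"):
            return False
        raise ConfigError(f"cannot parse boolean from {value!r}")
    if target_type is int:
        return int(value)
    if target_type is float:
        return float(value)
    return value


def load_config(path: str | Path | None = None,
                overrides: Dict[str, str] | None = None) -> RunConfig:
    """Build a RunConfig from an optional flat key-value file plus
    ``key=value`` overrides.  Unknown keys raise :class:`ConfigError`."""
    entries: Dict[str, str] = {}
    if path is not None:
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{ln}: expected key = value")
            k, _, v = line.partition("=")
            entries[k.strip()] = v.strip()
    if overrides:
        entries.update(overrides)

    sections = {"model": {}, "solver": {}, "metrics": {}}
    run: Dict[str, Any] = {}
    field_types = {ns: {f.name: type(getattr(cls(), f.name))
                        for f in dataclasses.fields(cls)}
                   for ns, cls in (("model", ModelParameters),
                                   ("solver", SolverSettings),
                                   ("metrics", MetricsConfig))}
    for key, raw in entries.items():
        if "." in key:
            ns, _, name = key.partition(".")
        else:
            ns, name = "run", key
        if ns in sections:
            if name not in field_types[ns]:
                raise ConfigError(f"unknown key {key!r}")
            sections[ns][name] = _coerce(raw, field_types[ns][name])
        elif ns == "run":
            if name == "duration_s":
                run["duration_s"] = float(raw)
            elif name == "i_app_pa":
                run["i_app_pa"] = float(raw)
            elif name == "seed":
                run["seed"] = int(raw)
            else:
                raise ConfigError(f"unknown key {key!r}")
        elif ns == "grid":
            if name == "gnap":
                run["gnap_grid"] = raw
            elif name == "gcan":
                run["gcan_grid"] = raw
            else:
                raise ConfigError(f"unknown key {key!r}")
        else:
            raise ConfigError(f"unknown key {key!r}")
    try:
        model = ModelParameters(**sections["model"])
    except (TypeError, InvalidParameterError) as e:
        raise ConfigError(f"bad model parameters: {e}") from e
    solver = SolverSettings(**sections["solver"])
    metrics = MetricsConfig(**sections["metrics"])
    # validate grids eagerly
    cfg = RunConfig(model=model, solver=solver, metrics=metrics, **run)
    parse_grid(cfg.gnap_grid)
    parse_grid(cfg.gcan_grid)
    return cfg


def save_manifest(cfg: RunConfig, path: str | Path,
                  extra: Dict[str, Any] | None = None) -> None:
    """Write the complete effective configuration as a flat key-value
    manifest."""
    flat = cfg.to_flat()
    if extra:
        flat.update(extra)
    with open(path, "w") as fh:
        for k in sorted(flat):
            fh.write(f"{k} = {flat[k]}\n")
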