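"""Run configuration, artifact writers/readers, and run metadata.

Tables, trajectories and maps are CSV; fixed points and run metadata are
JSON.  Every simulation output can be regenerated from its metadata file
alone (parameters + seed + method).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .model import Trajectory
from .params import ModelParameters, ScalingSpec, base_case, load_parameters
from .phenotype import VelocityMap
from .ssa import StochasticTrajectory

__all__ = ["RunConfig", "load_config", "parameter_hash", "write_metadata",
           "write_trajectory", "read_trajectory", "write_velocity_map",
           "read_velocity_map", "write_fixed_points"]

_CONFIG_KEYS = {
    "params_file", "overrides", "k_ecm", "n_star", "t_end", "seed",
    "subvolumes", "dt_record", "burn_in", "low_threshold", "high_threshold",
    "k_ecm_grid", "E_s_grid", "I_n", "C_s", "out_prefix",
}
_DEFAULTS = {"n_star": 3, "t_end": 1000.0, "dt_record": 0.5, "burn_in": 100.0,
             "low_threshold": 1.0, "high_threshold": 5.0, "subvolumes": 20,
             "seed": 0}


@dataclass
class RunConfig:
    """Validated simulation configuration."""

    params: ModelParameters
    overrides: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def __getattr__(self, key):
        opts = object.__getattribute__(self, "options")
        if key in opts:
            return opts[key]
        raise AttributeError(key)

    def to_dict(self) -> dict:
        d = dict(self.options)
        if self.overrides:
            d["overrides"] = dict(self.overrides)
        d["parameters"] = self.params.to_dict()
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys are rejected by name; overrides must address existing
    parameter or scaling fields.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise KeyError(f"unknown config key(s): {sorted(unknown)}")
    params = load_parameters(data["params_file"]) if "params_file" in data else base_case()
    overrides = dict(data.get("overrides", {}))
    if overrides:
        scaling_keys = {"n_star", "K_m", "K_r"}
        params = params.with_overrides(**{k: v for k, v in overrides.items()
                                          if k not in scaling_keys})
    options = dict(_DEFAULTS)
    options.update({k: v for k, v in data.items()
                    if k not in ("params_file", "overrides")})
    return RunConfig(params=params, overrides=overrides, options=options)


def parameter_hash(params: ModelParameters, scaling: ScalingSpec | None = None) -> str:
    payload = params.to_dict()
    if scaling is not None:
        payload["scaling"] = {"n_star": scaling.n_star, "K_m": scaling.K_m,
                              "K_r": scaling.K_r}
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_metadata(path: str | Path, params: ModelParameters, seed, method: str,
                   scaling: ScalingSpec | None = None, **extra) -> None:
    meta = {
        "method": method,
        "seed": seed,
        "parameter_hash": parameter_hash(params, scaling),
        "parameters": params.to_dict(),
    }
    if scaling is not None:
        meta["scaling"] = {"n_star": scaling.n_star, "K_m": scaling.K_m,
                           "K_r": scaling.K_r}
    meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2))


def write_trajectory(traj: Trajectory | StochasticTrajectory, path: str | Path) -> None:
    traj.to_dataframe().to_csv(path, index=False, float_format="%.12g")


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_velocity_map(vmap: VelocityMap, path: str | Path) -> None:
    """Rows = positions, columns = time bins; masked cells written empty."""
    vals = vmap.values.copy()
    if vmap.mask is not None:
        vals = vals.astype(object)
        vals[vmap.mask] = ""
    df = pd.DataFrame(vals)
    df.columns = [f"t{j}" for j in range(vmap.values.shape[1])]
    header = (f"# spatial_step={vmap.spatial_step} "
              f"frame_interval={vmap.frame_interval} units={vmap.units}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.12g")


def read_velocity_map(path: str | Path) -> VelocityMap:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(item.split("=") for item in header.lstrip("# ").split())
    values = df.to_numpy(dtype=float)
    mask = np.isnan(values)
    return VelocityMap(values=np.nan_to_num(values, nan=0.0),
                       spatial_step=float(meta["spatial_step"]),
                       frame_interval=float(meta["frame_interval"]),
                       units=meta["units"].strip(),
                       mask=mask if mask.any() else None)


def write_fixed_points(fixed_points, path: str | Path) -> None:
    out = []
    for fp in fixed_points:
        out.append({
            "n": fp.state.n, "s": fp.state.s, "m": fp.state.m,
            "x": fp.state.x, "r": fp.state.r, "p": fp.state.p,
            "v": fp.v, "stability": fp.stability,
            "eigenvalues": [complex(e).real for e in fp.eigenvalues],
            "residual": fp.residual,
        })
    Path(path).write_text(json.dumps(out, indent=2))
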