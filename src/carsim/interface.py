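"""Configuration handling, trajectory I/O and synthetic test fixtures.

Configs are TOML (YAML also accepted) with four tables::

    [grid]      N_r, dr
    [params]    every ModelParams field, verbatim keys
    [protocol]  kind, amplitude, diameter | radius, t_on, ...
    [run]       duration, save_every, safety?, dt_cap?, seed?

Unknown keys are rejected at every level.  Trajectories are stored in
HDF5 with one dataset per field and a JSON metadata attribute.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .core import (
    ModelParams,
    RadialGrid,
    build_grid,
    default_params,
    params_from_dict,
    params_to_dict,
)
from .illumination import LightProtocol, protocol_from_config
from .simulate import Trajectory

__all__ = [
    "RunConfig",
    "load_config",
    "emit_config",
    "config_hash",
    "save_trajectory",
    "load_trajectory",
    "make_fixture",
]


@dataclass
class RunConfig:
    """Everything a deterministic run needs; round-trips through TOML."""

    grid: RadialGrid
    params: ModelParams
    protocol: LightProtocol
    duration: float
    save_every: float
    safety: float = 0.4
    dt_cap: Optional[float] = None
    seed: Optional[int] = None


_RUN_KEYS = {"duration", "save_every", "safety", "dt_cap", "seed"}


def _parse_mapping(raw: dict) -> RunConfig:
    unknown = sorted(set(raw) - {"grid", "params", "protocol", "run"})
    if unknown:
        raise ValueError(f"unknown config sections: {unknown}")
    for section in ("grid", "protocol", "run"):
        if section not in raw:
            raise ValueError(f"missing config section [{section}]")
    gsec = dict(raw["grid"])
    extra = sorted(set(gsec) - {"N_r", "dr"})
    if extra:
        raise ValueError(f"unknown [grid] keys: {extra}")
    grid = build_grid(int(gsec["N_r"]), float(gsec["dr"]))
    params = (params_from_dict(raw["params"]) if "params" in raw
              else default_params())
    protocol = protocol_from_config(raw["protocol"])
    rsec = dict(raw["run"])
    extra = sorted(set(rsec) - _RUN_KEYS)
    if extra:
        raise ValueError(f"unknown [run] keys: {extra}")
    for key in ("duration", "save_every"):
        if key not in rsec:
            raise ValueError(f"missing required [run] key {key!r}")
    return RunConfig(
        grid=grid, params=params, protocol=protocol,
        duration=float(rsec["duration"]), save_every=float(rsec["save_every"]),
        safety=float(rsec.get("safety", 0.4)),
        dt_cap=(float(rsec["dt_cap"]) if rsec.get("dt_cap") is not None else None),
        seed=(int(rsec["seed"]) if rsec.get("seed") is not None else None),
    )


def load_config(path) -> RunConfig:
    """Load and validate a run config from a TOML or YAML file."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
    else:
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    return _parse_mapping(raw)


def _config_mapping(config: RunConfig) -> dict:
    proto = config.protocol
    psec = {"kind": proto.kind, "amplitude": proto.A, "radius": proto.rho,
            "w_s": proto.w_s}
    if proto.kind == "pulse_train":
        psec.update(t_on=proto.t_on, t_off=proto.t_off, n_cyc=proto.n_cyc)
    elif np.isfinite(proto.t_on):
        psec["t_on"] = proto.t_on
    run = {"duration": config.duration, "save_every": config.save_every,
           "safety": config.safety}
    if config.dt_cap is not None:
        run["dt_cap"] = config.dt_cap
    if config.seed is not None:
        run["seed"] = config.seed
    return {
        "grid": {"N_r": config.grid.N_r, "dr": config.grid.dr},
        "params": params_to_dict(config.params),
        "protocol": psec,
        "run": run,
    }


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def emit_toml(mapping: dict) -> str:
    """Minimal TOML emitter for the flat table-of-scalars config schema."""
    lines = []
    for table, record in mapping.items():
        lines.append(f"[{table}]")
        for key, value in record.items():
            lines.append(f"{key} = {_toml_value(value)}")
        lines.append("")
    return "\n".join(lines)


def emit_config(config: RunConfig) -> str:
    """Serialize a RunConfig to canonical TOML; parse(emit(c)) == emit-identity."""
    return emit_toml(_config_mapping(config))


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the canonical config (for logs)."""
    return hashlib.sha256(emit_config(config).encode()).hexdigest()[:12]


# -- trajectory I/O ---------------------------------------------------------

def save_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory to HDF5: /times, /chem/<species>, /mech/{U_r,V_r}."""
    import h5py

    from .chemistry import SPECIES

    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=traj.times)
        grp = fh.create_group("chem")
        for i, name in enumerate(SPECIES):
            grp.create_dataset(name, data=traj.chem[:, i])
        if traj.U is not None:
            mech = fh.create_group("mech")
            mech.create_dataset("U_r", data=traj.U)
            mech.create_dataset("V_r", data=traj.V)
        grid = traj.grid
        if hasattr(grid, "N_r"):
            grid_meta = {"kind": "radial", "N_r": grid.N_r, "dr": grid.dr}
        else:
            grid_meta = {"kind": "cartesian2d", "n": grid.n, "dx": grid.dx}
        proto = traj.protocol
        proto_meta = {"kind": proto.kind, "A": proto.A, "rho": proto.rho,
                      "w_s": proto.w_s, "t_on": proto.t_on,
                      "t_off": proto.t_off, "n_cyc": proto.n_cyc}
        fh.attrs["meta"] = json.dumps({
            "grid": grid_meta,
            "params": params_to_dict(traj.params),
            "protocol": proto_meta,
            **{k: v for k, v in traj.meta.items() if v is not None},
        }, default=float)


def load_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`save_trajectory`."""
    import h5py

    from .chemistry import SPECIES
    from .simulate import Grid2D

    with h5py.File(path, "r") as fh:
        times = fh["times"][...]
        chem = np.stack([fh["chem"][name][...] for name in SPECIES], axis=1)
        U = fh["mech/U_r"][...] if "mech" in fh else None
        V = fh["mech/V_r"][...] if "mech" in fh else None
        meta = json.loads(fh.attrs["meta"])
    gm = meta.pop("grid")
    if gm["kind"] == "radial":
        grid = build_grid(int(gm["N_r"]), float(gm["dr"]))
    else:
        grid = Grid2D(n=int(gm["n"]), dx=float(gm["dx"]))
    params = params_from_dict(meta.pop("params"))
    pm = meta.pop("protocol")
    t_on = pm["t_on"] if pm["t_on"] is not None else np.inf
    protocol = LightProtocol(kind=pm["kind"], A=pm["A"], rho=pm["rho"],
                             w_s=pm["w_s"],
                             t_on=(np.inf if t_on in ("inf", None) else float(t_on)),
                             t_off=float(pm["t_off"]), n_cyc=int(pm["n_cyc"]))
    return Trajectory(times=times, chem=chem, U=U, V=V, grid=grid,
                      params=params, protocol=protocol, meta=meta)


# -- synthetic fixtures for the analysis metrics ----------------------------

def make_fixture(kind: str, **kw):
    """Deterministic synthetic inputs with documented ground truth.

    kinds:
      annulus_velocity(grid, inner, outer, speed) -> V_r field whose CAR
          width at any cutoff < speed is outer - inner and mean speed is
          ``speed``.
      step_density(grid, radius, height) -> C_Btot field whose network
          radius at any threshold < height equals ``radius`` to within one
          grid cell.
      sqrt_growth_series(n, noise, seed, t_max=100, prefactor=8) ->
          (times, radii) with R = prefactor * sqrt(t) * (multiplicative
          lognormal noise); growth exponent 0.5.
    """
    if kind == "annulus_velocity":
        grid, inner, outer, speed = kw["grid"], kw["inner"], kw["outer"], kw["speed"]
        V = np.where((grid.r >= inner) & (grid.r <= outer), speed, 0.0)
        return V
    if kind == "step_density":
        grid, radius, height = kw["grid"], kw["radius"], kw["height"]
        return np.where(grid.r <= radius, height, 0.0)
    if kind == "sqrt_growth_series":
        n, noise, seed = kw["n"], kw["noise"], kw["seed"]
        t_max = kw.get("t_max", 100.0)
        prefactor = kw.get("prefactor", 8.0)
        rng = np.random.default_rng(seed)
        t = np.linspace(t_max / n, t_max, n)
        R = prefactor * np.sqrt(t) * np.exp(noise * rng.standard_normal(n))
        return t, R
    raise ValueError(f"unknown fixture kind {kind!r}")
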