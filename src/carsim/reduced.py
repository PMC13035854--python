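"""Fixed-chemistry contraction model: imposed density, one mechanical solve.

Chemical reactions are switched off; a user-defined bound-Tcb2 density
profile and a light-shaped Ca2+ activation profile are imposed, and the
instantaneous contraction velocity V_r = f_r / Gamma is evaluated at
U_r = 0.  This isolates the mechanism behind the reversal of contraction
direction: the flatness parameter ``a`` controls the relative accumulation
of bound Tcb2 at the network boundary, whose stiffness gradient drives an
outward velocity lobe interior to the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ModelParams, RadialGrid
from .mechanics import ElasticCoefficients, elastic_force, moduli_fields, \
    velocity_from_force

__all__ = [
    "DensityProfileSpec",
    "ReducedConfig",
    "synthetic_density",
    "activation_profile",
    "reduced_velocity",
    "extrema_sweep",
]


@dataclass
class DensityProfileSpec:
    """Plateau + Gaussian boundary-peak density profile.

    ``a`` in (0, 1] is the flatness: a = 1 is a flat plateau of height
    C_max, small a concentrates the density in a boundary peak of width
    ``s_width`` at the network edge ``r_star``.
    """

    a: float            # flatness, (0, 1]
    r_star: float       # network boundary radius (um)
    s_width: float      # boundary-peak width (um)
    C_max: float        # peak concentration (uM)

    def validate(self, grid: RadialGrid) -> "DensityProfileSpec":
        if not (0.0 < self.a <= 1.0):
            raise ValueError(f"flatness a must be in (0, 1], got {self.a}")
        if not (0.0 < self.r_star < grid.R_max):
            raise ValueError(
                f"r_star must lie inside the grid (0, {grid.R_max}), "
                f"got {self.r_star}"
            )
        if self.s_width <= 0:
            raise ValueError(f"s_width must be positive, got {self.s_width}")
        if self.C_max < 0:
            raise ValueError(f"C_max must be >= 0, got {self.C_max}")
        return self


def synthetic_density(spec: DensityProfileSpec, grid: RadialGrid) -> np.ndarray:
    """Bound-Tcb2 density: plateau a*C_max with a Gaussian peak to C_max at
    r_star, decaying smoothly to zero over s_width beyond r_star.

    The plateau-to-peak ratio at r = 0 equals ``a`` when r_star >> s_width.
    """
    spec.validate(grid)
    r = grid.r
    bump = np.exp(-((r - spec.r_star) ** 2) / (2.0 * spec.s_width ** 2))
    inside = spec.C_max * (spec.a + (1.0 - spec.a) * bump)
    outside = spec.C_max * bump
    return np.where(r <= spec.r_star, inside, outside)


def activation_profile(grid: RadialGrid, rho_light: float, w: float) -> np.ndarray:
    """Sigmoidal light-shaped Ca2+ activation phi(r) = 1/(1+exp((r-rho)/w))."""
    if w <= 0:
        raise ValueError(f"activation width w must be positive, got {w}")
    x = np.clip((grid.r - rho_light) / w, -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(x))


@dataclass
class ReducedConfig:
    """Base configuration for reduced-model solves and sweeps."""

    profile: DensityProfileSpec
    rho_light: float    # light profile radius (um)
    w: float            # light profile width (um)
    params: ModelParams


def reduced_velocity(C_Btot, ca_profile, params: ModelParams,
                     grid: RadialGrid) -> np.ndarray:
    """Instantaneous radial velocity at U_r = 0 for an imposed density and
    Ca activation profile (the Ca-loaded fraction phi in [0, 1])."""
    C = np.asarray(C_Btot, dtype=float)
    phi = np.asarray(ca_profile, dtype=float)
    lam, mu = moduli_fields(C, params)
    g = params.g_max * phi
    f = elastic_force(np.zeros_like(C), ElasticCoefficients(lam, mu, g), grid)
    return velocity_from_force(f, params)


def _solve(cfg: ReducedConfig, grid: RadialGrid) -> np.ndarray:
    C = synthetic_density(cfg.profile, grid)
    phi = activation_profile(grid, cfg.rho_light, cfg.w)
    return reduced_velocity(C, phi, cfg.params, grid)


_SWEEPABLE = ("a", "r_star", "w", "mu0")


def extrema_sweep(param_name: str, values: Sequence[float],
                  base: ReducedConfig, grid: RadialGrid) -> pd.DataFrame:
    """Sweep one parameter; report max and min radial velocity per value.

    ``param_name`` is one of 'a', 'r_star' (density profile), 'w' (light
    width) or 'mu0' (stiffness slope).  Returns a DataFrame with columns
    (value, V_max, V_min).
    """
    if param_name not in _SWEEPABLE:
        raise ValueError(
            f"unknown sweep parameter {param_name!r}; expected one of {_SWEEPABLE}"
        )
    rows = []
    for v in values:
        cfg = base
        if param_name in ("a", "r_star"):
            cfg = replace(base, profile=replace(base.profile, **{param_name: float(v)}))
        elif param_name == "w":
            cfg = replace(base, w=float(v))
        elif param_name == "mu0":
            cfg = replace(base, params=replace(base.params, mu0=float(v)))
        V = _solve(cfg, grid)
        rows.append({"value": float(v), "V_max": float(V.max()),
                     "V_min": float(V.min())})
    return pd.DataFrame(rows)
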