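"""Metrics of network growth and contraction: radius, growth exponent,
Ca2+-driven active region (CAR) width and speed, kymographs, tracer advection.

The CAR is the mechanically active annulus near the network boundary,
defined operationally as the radial extent where |V_r| exceeds a cutoff
(0.2 um/s by convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RadialGrid

__all__ = [
    "CarMetrics",
    "network_radius",
    "growth_exponent",
    "car_metrics",
    "kymograph",
    "advect_tracer",
]


@dataclass
class CarMetrics:
    """Width and speed of the Ca2+-driven active region.

    ``width = outer - inner`` is the extent of the outermost contiguous
    region where |V_r| > cutoff; ``mean_speed`` is the mean |V_r| over that
    region; ``total_width`` additionally counts all disjoint super-cutoff
    regions.
    """

    width: float        # um
    mean_speed: float   # um/s
    inner: float        # um
    outer: float        # um
    cutoff: float       # um/s
    total_width: float  # um


def network_radius(C_Btot, grid: RadialGrid, threshold: float) -> float:
    """Outermost radius where the bound-Tcb2 density reaches ``threshold``.

    Linearly interpolated between nodes; 0 if the field is below threshold
    everywhere.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    C = np.asarray(C_Btot, dtype=float)
    above = C >= threshold
    if not above.any():
        return 0.0
    i = int(np.max(np.nonzero(above)))
    if i == len(C) - 1:
        return float(grid.r[-1])
    # crossing between nodes i (above) and i+1 (below)
    frac = (C[i] - threshold) / (C[i] - C[i + 1])
    return float(grid.r[i] + frac * grid.dr)


def growth_exponent(times, radii) -> float:
    """Least-squares slope of log R against log t (0.5 = diffusion-limited)."""
    t = np.asarray(times, dtype=float)
    R = np.asarray(radii, dtype=float)
    if t.shape != R.shape or t.size < 5:
        raise ValueError("need >= 5 matched (time, radius) points")
    if np.any(t <= 0) or np.any(R <= 0):
        raise ValueError("times and radii must be strictly positive")
    beta, _ = np.polyfit(np.log(t), np.log(R), 1)
    return float(beta)


def _contiguous_regions(mask: np.ndarray):
    """(start, stop) index pairs of runs of True, stop inclusive."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts, stops))


def car_metrics(V_r, grid: RadialGrid, cutoff: float = 0.2) -> CarMetrics:
    """CAR width and mean speed at the given |V_r| cutoff (um/s).

    Width is measured over the outermost contiguous super-cutoff region
    (the peripheral active annulus), using the first and last super-cutoff
    node radii as its edges; ``total_width`` sums all disjoint regions.
    Invariant under a sign flip of V_r.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    speed = np.abs(np.asarray(V_r, dtype=float))
    regions = _contiguous_regions(speed > cutoff)
    if not regions:
        return CarMetrics(0.0, 0.0, 0.0, 0.0, cutoff, 0.0)
    total = sum(float(grid.r[hi] - grid.r[lo]) for lo, hi in regions)
    lo, hi = regions[-1]
    inner, outer = float(grid.r[lo]), float(grid.r[hi])
    mean_speed = float(speed[lo:hi + 1].mean())
    return CarMetrics(width=outer - inner, mean_speed=mean_speed,
                      inner=inner, outer=outer, cutoff=cutoff,
                      total_width=total)


def kymograph(trajectory, field_name: str) -> np.ndarray:
    """Radius x time matrix of one field's saved frames."""
    frames = trajectory.field_frames(field_name)
    if frames.ndim != 2:
        raise ValueError("kymographs are defined for radial trajectories")
    return frames.T.copy()


def advect_tracer(trajectory, R0: float, coupling: str = "network"):
    """Integrate a tracer dR/dt = V_r(R, t) through the saved velocity frames.

    ``coupling='network'`` advects with the network velocity; ``'free'`` is
    a non-interacting reference that stays put (useful as a control).
    Velocity is interpolated linearly in radius and held piecewise-constant
    between frames (midpoint value).  Returns (times, positions, exited)
    where ``exited`` flags a tracer that left the grid (series truncated).
    """
    if coupling not in ("network", "free"):
        raise ValueError(f"unknown coupling {coupling!r}")
    grid = trajectory.grid
    times = trajectory.times
    if not (0.0 <= R0 <= grid.R_max):
        raise ValueError(f"R0 = {R0} outside the grid [0, {grid.R_max}]")
    if coupling == "free":
        return times.copy(), np.full(len(times), float(R0)), False
    V = trajectory.field_frames("V_r")
    pos = [float(R0)]
    exited = False
    for j in range(len(times) - 1):
        dt = times[j + 1] - times[j]
        v_mid = 0.5 * (np.interp(pos[-1], grid.r, V[j])
                       + np.interp(pos[-1], grid.r, V[j + 1]))
        new = pos[-1] + v_mid * dt
        if not (0.0 <= new <= grid.R_max):
            exited = True
            break
        pos.append(new)
    return times[:len(pos)].copy(), np.asarray(pos), exited
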