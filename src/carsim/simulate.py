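"""Time integration of the coupled chemomechanical system.

Heun's predictor-corrector scheme with a fixed step chosen from the
stability limits of diffusion, the fastest linearized reaction, and the
explicit overdamped mechanics.  Chemical species obey no-flux Neumann
boundary conditions; the displacement is pinned to zero at the origin
(symmetry) and the outer boundary (Dirichlet).

Two modes:

* :func:`run_simulation` — the full radial (azimuthally symmetric)
  chemistry + mechanics model.
* :func:`run_chem2d` — chemistry only on a Cartesian 2D grid, for
  arbitrary illumination masks (star shapes, moving spots).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .chemistry import (
    ChemFields,
    SPECIES,
    binding_site_availability,
    cylindrical_laplacian,
    reaction_rates_array,
    species_diffusivities,
)
from .core import FieldState, ModelParams, RadialGrid, validate_params
from .illumination import LightProtocol, mask_at
from .mechanics import (
    MechFields,
    ElasticCoefficients,
    elastic_force,
    moduli_fields,
    rest_strain_field,
    velocity_from_force,
)

__all__ = [
    "IntegrationError",
    "Trajectory",
    "Grid2D",
    "stable_dt",
    "initial_chem",
    "heun_step",
    "run_simulation",
    "run_chem2d",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a NaN or negative concentration."""


@dataclass(frozen=True)
class Grid2D:
    """Uniform Cartesian grid of n x n cells with spacing dx (um), centered."""

    n: int
    dx: float

    @property
    def xy(self) -> np.ndarray:
        return (np.arange(self.n) - (self.n - 1) / 2.0) * self.dx

    def radii(self) -> np.ndarray:
        X, Y = np.meshgrid(self.xy, self.xy)
        return np.hypot(X, Y)


@dataclass
class Trajectory:
    """Saved frames of a run plus everything needed to re-run it."""

    times: np.ndarray                 # (n_save,) strictly increasing
    chem: np.ndarray                  # (n_save, 8, ...) concentration frames
    U: Optional[np.ndarray]           # (n_save, n_nodes) or None (2D mode)
    V: Optional[np.ndarray]           # (n_save, n_nodes) or None
    grid: object                      # RadialGrid or Grid2D
    params: ModelParams
    protocol: LightProtocol
    meta: dict = field(default_factory=dict)

    def field_frames(self, name: str) -> np.ndarray:
        """Frames of one field: chemical species by name, or U_r / V_r."""
        if name in SPECIES:
            return self.chem[:, SPECIES.index(name)]
        if name == "C_Btot":
            return self.chem[:, 6] + self.chem[:, 7]
        if name == "U_r":
            if self.U is None:
                raise KeyError("trajectory has no mechanics")
            return self.U
        if name == "V_r":
            if self.V is None:
                raise KeyError("trajectory has no mechanics")
            return self.V
        raise KeyError(f"unknown field {name!r}")

    def state(self, i: int) -> FieldState:
        mech = (MechFields(self.U[i].copy(), self.V[i].copy())
                if self.U is not None else MechFields.zeros(self.chem.shape[-1]))
        return FieldState(t=float(self.times[i]),
                          chem=ChemFields(self.chem[i].copy()), mech=mech)


# --------------------------------------------------------------------------
def _linearized_rate_bound(p: ModelParams, amplitude: float) -> float:
    """Upper bound on the fastest per-capita consumption rate of any species."""
    S_max = (p.sigma0 + p.C_sat) ** 2 / (4.0 * p.C_sat)
    C_scale = max(p.C_Ca_tot, 1e-30)
    return max(
        p.k_ph * amplitude + p.k_offD,                  # C_E
        p.k_onD * p.C_D_tot + p.k_onT * p.C_T_tot,      # C_C
        p.k_onD * C_scale,                              # C_D
        p.k_onT * C_scale + p.k_bind0 * S_max,          # C_F0
        p.k_offT + p.k_bind * S_max,                    # C_FC
        p.k_onT * C_scale + p.k_u0,                     # C_B0
        p.k_offT + p.k_uCa,                             # C_BC
    )


def stable_dt(params: ModelParams, grid, safety: float,
              amplitude: float = 1.0, dt_cap: Optional[float] = None) -> float:
    """Stable fixed step: safety * min(diffusion, reaction, mechanics) limits.

    dt = safety * min( dr^2 / (4 D_max),
                       1 / R_rate,
                       Gamma dr^2 / (4 (lam + 2 mu)_max) )

    where R_rate bounds the fastest linearized reaction (photolysis at the
    given light amplitude, chelation and Tcb2 loading at pool
    concentrations, network kinetics at peak site availability) and the
    moduli are evaluated at the saturation density C_sat.  ``grid`` may be
    a RadialGrid or Grid2D; an optional user cap is applied last.
    """
    if not (0.0 < safety <= 1.0):
        raise ValueError(f"safety must be in (0, 1], got {safety}")
    p = params
    dr = grid.dr if hasattr(grid, "dr") else grid.dx
    limits = []
    D_max = p.D_max()
    if D_max > 0:
        limits.append(dr * dr / (4.0 * D_max))
    rate = _linearized_rate_bound(p, amplitude)
    if rate > 0:
        limits.append(1.0 / rate)
    stiff_max = (p.lambda_ratio + 2.0) * (p.mu_floor + p.mu0 * p.C_sat ** p.p_stiff)
    limits.append(p.Gamma * dr * dr / (4.0 * stiff_max))
    dt = safety * min(limits)
    if dt_cap is not None:
        dt = min(dt, dt_cap)
    return dt


def initial_chem(params: ModelParams, n_nodes: int, shape=None) -> np.ndarray:
    """Uniform initial state: all Tcb2 free, all Ca2+ chelated.

    C_E = C_Ca_tot, C_D = C_D_tot - C_Ca_tot (2:1 chelator:Ca loading in
    the defaults), C_F0 = C_T_tot, everything else zero.
    """
    if params.C_D_tot < params.C_Ca_tot:
        raise ValueError("C_D_tot must be >= C_Ca_tot so all Ca starts chelated")
    shp = (len(SPECIES),) + (tuple(shape) if shape is not None else (n_nodes,))
    y = np.zeros(shp)
    y[SPECIES.index("C_E")] = params.C_Ca_tot
    y[SPECIES.index("C_D")] = params.C_D_tot - params.C_Ca_tot
    y[SPECIES.index("C_F0")] = params.C_T_tot
    return y


def _check_state(y: np.ndarray, t: float, tol: float = -1e-9) -> None:
    """Abort (never clip) on NaN or beyond-roundoff negative concentrations."""
    per_node = int(np.prod(y.shape[1:]))
    if not np.all(np.isfinite(y)):
        flat = int(np.argmax(~np.isfinite(y)))
        raise IntegrationError(
            f"non-finite value in field {SPECIES[flat // per_node]} at node "
            f"{flat % per_node}, t = {t:.6g} s"
        )
    m = y.min()
    if m < tol:
        flat = int(np.argmin(y))
        raise IntegrationError(
            f"negative concentration {m:.3e} uM in field "
            f"{SPECIES[flat // per_node]} at node {flat % per_node}, "
            f"t = {t:.6g} s (reduce dt / safety)"
        )


def _mech_velocity(y: np.ndarray, p: ModelParams, grid: RadialGrid,
                   U: np.ndarray) -> np.ndarray:
    C_B0, C_BC = y[6], y[7]
    lam, mu = moduli_fields(C_B0 + C_BC, p)
    g = rest_strain_field(C_B0, C_BC, p)
    f = elastic_force(U, ElasticCoefficients(lam, mu, g), grid)
    return velocity_from_force(f, p)


def _rhs_radial(y, U, light, p, grid, D, mechanics=True):
    dy = reaction_rates_array(y, light, p)
    dy[:6] += D[:6, None] * cylindrical_laplacian(y[:6], grid)
    dU = _mech_velocity(y, p, grid, U) if mechanics else None
    return dy, dU


def heun_step(state: FieldState, t: float, dt: float,
              protocol: LightProtocol, params: ModelParams,
              grid: RadialGrid) -> FieldState:
    """One Heun predictor-corrector step of the coupled system.

    Chemical fields advance under reactions + diffusion, the displacement
    under dU/dt = V_r with the force balance re-evaluated at both stages.
    The returned state carries the instantaneous velocity of the new
    configuration.  Raises :class:`IntegrationError` on NaN or negative
    concentrations.
    """
    p = params
    D = species_diffusivities(p)
    y = state.chem.data
    U = state.mech.U_r
    prof = protocol.radial_profile(grid.r)

    k1y, k1U = _rhs_radial(y, U, prof * protocol.gate(t), p, grid, D)
    y_p = y + dt * k1y
    U_p = U + dt * k1U
    k2y, k2U = _rhs_radial(y_p, U_p, prof * protocol.gate(t + dt), p, grid, D)
    y_new = y + 0.5 * dt * (k1y + k2y)
    U_new = U + 0.5 * dt * (k1U + k2U)
    U_new[0] = U_new[-1] = 0.0
    _check_state(y_new, t + dt)
    V_new = _mech_velocity(y_new, p, grid, U_new)
    return FieldState(t=t + dt, chem=ChemFields(y_new),
                      mech=MechFields(U_new, V_new))


def _save_indices(duration: float, dt: float, save_every: float):
    n_steps = int(np.ceil(duration / dt - 1e-9))
    n_save = int(np.floor(duration / save_every + 1e-9))
    idx = sorted({min(max(int(round(k * save_every / dt)), 1), n_steps)
                  for k in range(1, n_save + 1)} | {n_steps})
    return n_steps, idx


def run_simulation(config) -> "Trajectory":
    """Integrate the coupled radial model from the uniform initial state.

    ``config`` is any object with attributes ``grid`` (RadialGrid),
    ``params`` (ModelParams), ``protocol`` (LightProtocol), ``duration``
    (s), ``save_every`` (s), and optionally ``safety`` (default 0.4),
    ``dt_cap`` and ``seed`` — e.g. an :class:`carsim.interface.RunConfig`.
    Deterministic given the config.
    """
    grid: RadialGrid = config.grid
    p: ModelParams = validate_params(config.params)
    protocol: LightProtocol = config.protocol
    duration = float(config.duration)
    save_every = float(config.save_every)
    safety = float(getattr(config, "safety", 0.4))
    dt_cap = getattr(config, "dt_cap", None)
    if protocol.kind != "mask2d" and protocol.rho >= grid.R_max:
        raise ValueError(
            f"illumination radius {protocol.rho} um must be strictly inside "
            f"R_max = {grid.R_max} um"
        )
    dt = stable_dt(p, grid, safety, amplitude=protocol.A, dt_cap=dt_cap)
    D = species_diffusivities(p)
    prof = protocol.radial_profile(grid.r)
    y = initial_chem(p, grid.n_nodes)
    U = np.zeros(grid.n_nodes)

    n_steps, save_idx = _save_indices(duration, dt, save_every)
    frames_c, frames_U, frames_V, times = [], [], [], []

    def save(step):
        times.append(step * dt)
        frames_c.append(y.copy())
        frames_U.append(U.copy())
        frames_V.append(_mech_velocity(y, p, grid, U))

    save_set = set(save_idx)
    save(0)  # always keep the initial frame

    from ._kernel import HAVE_NUMBA, integrate_block, pack_params

    if HAVE_NUMBA:
        P = pack_params(p)
        step_t = np.arange(n_steps) * dt
        gate1 = protocol.gate_array(step_t)
        gate2 = protocol.gate_array(step_t + dt)
        start = 0
        for stop in save_idx:
            status, k, s, node = integrate_block(
                y, U, P, grid.r, grid.dr, D, prof,
                gate1[start:stop], gate2[start:stop], dt)
            if status != 0:
                what = ("negative concentration" if status == 1
                        else "non-finite value")
                raise IntegrationError(
                    f"{what} in field {SPECIES[s]} at node {node}, "
                    f"t = {(start + k + 1) * dt:.6g} s (reduce dt / safety)")
            start = stop
            save(stop)
        return _finish(times, frames_c, frames_U, frames_V, grid, p,
                       protocol, dt, safety, duration, save_every, config)

    next_check = 0
    for step in range(n_steps):
        t = step * dt
        k1y, k1U = _rhs_radial(y, U, prof * protocol.gate(t), p, grid, D)
        y_p = y + dt * k1y
        U_p = U + dt * k1U
        k2y, k2U = _rhs_radial(y_p, U_p, prof * protocol.gate(t + dt),
                               p, grid, D)
        y += 0.5 * dt * (k1y + k2y)
        U += 0.5 * dt * (k1U + k2U)
        U[0] = U[-1] = 0.0
        if step >= next_check:
            try:
                _check_state(y, t + dt)
            except IntegrationError as err:
                raise IntegrationError(f"{err} (step {step + 1})") from None
            next_check = step + 25
        if (step + 1) in save_set:
            save(step + 1)

    return _finish(times, frames_c, frames_U, frames_V, grid, p, protocol,
                   dt, safety, duration, save_every, config)


def _finish(times, frames_c, frames_U, frames_V, grid, p, protocol, dt,
            safety, duration, save_every, config) -> "Trajectory":
    meta = {
        "dt": dt, "safety": safety, "duration": duration,
        "save_every": save_every, "seed": getattr(config, "seed", None),
        "mode": "radial",
    }
    return Trajectory(times=np.asarray(times), chem=np.asarray(frames_c),
                      U=np.asarray(frames_U), V=np.asarray(frames_V),
                      grid=grid, params=p, protocol=protocol, meta=meta)


# -- 2D chemistry-only mode -------------------------------------------------

def _laplacian_2d(f: np.ndarray, dx: float) -> np.ndarray:
    """Flux-form 5-point Laplacian with no-flux edges; exactly conservative.

    Acts on the last two axes (stacks allowed).
    """
    out = np.zeros_like(f)
    gx = np.diff(f, axis=-1)
    out[..., :, :-1] += gx
    out[..., :, 1:] -= gx
    gy = np.diff(f, axis=-2)
    out[..., :-1, :] += gy
    out[..., 1:, :] -= gy
    return out / (dx * dx)


def run_chem2d(protocol: LightProtocol, params: ModelParams, grid: Grid2D,
               duration: float, save_every: float,
               safety: float = 0.4, dt_cap: Optional[float] = None) -> Trajectory:
    """Chemistry-only integration on a Cartesian 2D grid (mechanics disabled).

    Supports arbitrary 2D masks (mask2d protocols, including time-indexed
    frames) as well as radial protocols evaluated on the 2D radius map —
    the latter is what the 2D/1D equivalence check uses.
    """
    p = validate_params(params)
    dt = stable_dt(p, grid, safety, amplitude=protocol.A, dt_cap=dt_cap)
    D = species_diffusivities(p)

    static_mask = None
    if protocol.kind == "mask2d":
        m = protocol.mask
        if m.shape[0] == 1 or not np.isfinite(protocol.frame_dt):
            static_mask = protocol.A * m[0]
        if protocol.mask.shape[-2:] != (grid.n, grid.n):
            raise ValueError(
                f"mask shape {protocol.mask.shape[-2:]} does not match "
                f"grid ({grid.n}, {grid.n})"
            )
    else:
        static_mask = protocol.radial_profile(grid.radii())

    def light_at(t: float) -> np.ndarray:
        if static_mask is not None:
            return static_mask * protocol.gate(t)
        return mask_at(protocol, t)

    y = initial_chem(p, None, shape=(grid.n, grid.n))
    n_steps, save_idx = _save_indices(duration, dt, save_every)
    frames, times = [], []
    save_set = set(save_idx)
    frames.append(y.copy())
    times.append(0.0)
    for step in range(n_steps):
        t = step * dt
        L1 = light_at(t)
        k1 = reaction_rates_array(y, L1, p)
        k1[:6] += D[:6, None, None] * _laplacian_2d(y[:6], grid.dx)
        y_p = y + dt * k1
        L2 = light_at(t + dt)
        k2 = reaction_rates_array(y_p, L2, p)
        k2[:6] += D[:6, None, None] * _laplacian_2d(y_p[:6], grid.dx)
        y += 0.5 * dt * (k1 + k2)
        if step % 25 == 0:
            _check_state(y, t + dt)
        if (step + 1) in save_set:
            frames.append(y.copy())
            times.append((step + 1) * dt)
    _check_state(y, n_steps * dt)
    meta = {"dt": dt, "safety": safety, "duration": duration,
            "save_every": save_every, "mode": "chem2d"}
    return Trajectory(times=np.asarray(times), chem=np.asarray(frames),
                      U=None, V=None, grid=grid, params=p,
                      protocol=protocol, meta=meta)
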