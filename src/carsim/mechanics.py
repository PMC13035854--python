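"""Overdamped, azimuthally symmetric linear elasticity with chemical coupling.

The gel is a linearly elastic solid whose Lame coefficients grow with the
local bound-Tcb2 density and whose isotropic rest strain g (the strain at
which the material is locally stress-free) is shifted negative in
proportion to the Ca-loaded fraction of bound Tcb2 — Ca binding shortens
the monomer rest length, so a Ca-loaded region wants to contract.  Motion
is overdamped: the radial velocity instantaneously balances the elastic
force against viscous drag, V_r = f_r / Gamma.

Discretization is variational: strains live on the cells between nodes,
the energy is a cell quadrature, and the nodal force is the exact analytic
gradient of that discrete energy.  This keeps the spatially varying
coefficients inside the derivative (the source of the density-gradient
forces that reverse the contraction direction) and guarantees that
overdamped relaxation never increases the energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ModelParams, RadialGrid

__all__ = [
    "MechFields",
    "ElasticCoefficients",
    "moduli_fields",
    "rest_strain_field",
    "elastic_force",
    "elastic_energy",
    "velocity_from_force",
]


@dataclass
class MechFields:
    """Radial displacement and velocity fields on the grid nodes."""

    U_r: np.ndarray  # um
    V_r: np.ndarray  # um/s

    @classmethod
    def zeros(cls, n_nodes: int) -> "MechFields":
        return cls(U_r=np.zeros(n_nodes), V_r=np.zeros(n_nodes))

    def copy(self) -> "MechFields":
        return MechFields(self.U_r.copy(), self.V_r.copy())


@dataclass
class ElasticCoefficients:
    """Nodal Lame parameter fields and rest-strain field."""

    lam: np.ndarray  # stress
    mu: np.ndarray   # stress
    g: np.ndarray    # dimensionless, g_max <= g <= 0


def moduli_fields(C_Btot, params: ModelParams):
    """Lame fields from the bound-Tcb2 density.

    mu = mu_floor + mu0 * C_Btot^p_stiff (denser gel is stiffer, with a
    small background modulus so the force balance stays regular where the
    network vanishes); lam = lambda_ratio * mu.
    """
    C = np.asarray(C_Btot, dtype=float)
    mu = params.mu_floor + params.mu0 * C ** params.p_stiff
    lam = params.lambda_ratio * mu
    return lam, mu


def rest_strain_field(C_B0, C_BC, params: ModelParams) -> np.ndarray:
    """Isotropic rest strain g = g_max * phi, phi the Ca-loaded bound fraction.

    Rest length decreases linearly with the fraction of Ca-loaded bound
    Tcb2; g = 0 (no spontaneous contraction) where there is no network.
    """
    C_B0 = np.asarray(C_B0, dtype=float)
    C_BC = np.asarray(C_BC, dtype=float)
    tot = C_B0 + C_BC
    phi = np.zeros_like(tot)
    np.divide(C_BC, tot, out=phi, where=tot > 0)
    return params.g_max * phi


def _cell_quantities(U_r, coeff: ElasticCoefficients, grid: RadialGrid):
    """Strains, coefficients and weights on the N_r cells between nodes."""
    U = np.asarray(U_r, dtype=float)
    r = grid.r
    dr = grid.dr
    eps_rr = np.diff(U) / dr
    r_sum = r[:-1] + r[1:]                    # 2 * r_c
    eps_tt = (U[:-1] + U[1:]) / r_sum
    lam_c = 0.5 * (coeff.lam[:-1] + coeff.lam[1:])
    mu_c = 0.5 * (coeff.mu[:-1] + coeff.mu[1:])
    g_c = 0.5 * (coeff.g[:-1] + coeff.g[1:])
    w_c = np.pi * r_sum * dr                  # 2 pi r_c dr
    return eps_rr, eps_tt, lam_c, mu_c, g_c, w_c, r_sum


def elastic_energy(U_r, coeff: ElasticCoefficients, grid: RadialGrid) -> float:
    """Total elastic energy E = int [ lam/2 tr(e-gI)^2 + mu ||e-gI||^2 ] 2 pi r dr.

    e = diag(eps_rr, eps_tt) is the plane (rr, tt) strain of the thin
    sample.  E > 0 at U = 0 whenever g != 0: Ca binding loads the spring
    before any motion occurs.
    """
    eps_rr, eps_tt, lam_c, mu_c, g_c, w_c, _ = _cell_quantities(U_r, coeff, grid)
    d_rr = eps_rr - g_c
    d_tt = eps_tt - g_c
    dens = 0.5 * lam_c * (d_rr + d_tt) ** 2 + mu_c * (d_rr ** 2 + d_tt ** 2)
    return float(w_c @ dens)


def elastic_force(U_r, coeff: ElasticCoefficients, grid: RadialGrid) -> np.ndarray:
    """Radial elastic force density f_r (stress/um) at the grid nodes.

    Analytic gradient of :func:`elastic_energy`:
    f_i = -(1 / (2 pi r_i dr)) dE/dU_i, which is the second-order discrete
    form of d_r sigma_rr + (sigma_rr - sigma_tt)/r with the inhomogeneous
    lam(r), mu(r) kept inside the derivative.  Boundary nodes (U fixed to 0)
    get f = 0.
    """
    eps_rr, eps_tt, lam_c, mu_c, g_c, w_c, r_sum = _cell_quantities(
        U_r, coeff, grid
    )
    tr = eps_rr + eps_tt - 2.0 * g_c
    sig_rr = lam_c * tr + 2.0 * mu_c * (eps_rr - g_c)
    sig_tt = lam_c * tr + 2.0 * mu_c * (eps_tt - g_c)
    dr = grid.dr
    # dE/dU_i = w_{i-1} (sig_rr/dr + sig_tt/(2 r_c))_{i-1}
    #         + w_i    (-sig_rr/dr + sig_tt/(2 r_c))_i
    a = w_c * (sig_rr / dr + sig_tt / r_sum)      # cell contribution to node i+1
    b = w_c * (-sig_rr / dr + sig_tt / r_sum)     # cell contribution to node i
    f = np.zeros_like(np.asarray(U_r, dtype=float))
    f[1:-1] = -(a[:-1] + b[1:]) / (2.0 * np.pi * grid.r[1:-1] * dr)
    return f


def velocity_from_force(f_r, params: ModelParams) -> np.ndarray:
    """Instantaneous force balance V_r = f_r / Gamma, pinned at both boundaries."""
    if params.Gamma <= 0:
        raise ValueError(f"Gamma must be positive, got {params.Gamma}")
    V = np.asarray(f_r, dtype=float) / params.Gamma
    V = V.copy()
    V[0] = 0.0
    V[-1] = 0.0
    return V
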