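"""Reaction terms and diffusion operators for the eight-species network.

Species
-------
C_C   free Ca2+
C_D   viable unbound chelator (DMNP-EDTA)
C_E   Ca-loaded chelator complex
C_X   degraded chelator (photolysis by-product, kept for bookkeeping)
C_F0  diffusing Tcb2 without Ca2+
C_FC  diffusing Tcb2 with Ca2+
C_B0  network-bound Tcb2 without Ca2+
C_BC  network-bound Tcb2 with Ca2+

Reactions
---------
photolysis       E --light--> C + (1 - f_deg) D + f_deg X     rate k_ph * L * C_E
chelation        D + C <-> E                                  (k_onD, k_offD)
Ca exchange      F0 + C <-> FC,  B0 + C <-> BC                (k_onT, k_offT)
network joining  FC -> BC (k_bind * S),  F0 -> B0 (k_bind0 * S, slow)
network leaving  B0 -> F0 (k_u0),  BC -> FC (k_uCa < k_u0)

Bound species do not diffuse; diffusing species are not advected by the
network (low Peclet number).  S(C) is a non-monotone availability of
binding sites: bound Tcb2 creates new sites but saturates sterically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ModelParams, RadialGrid

__all__ = [
    "SPECIES",
    "DIFFUSING",
    "ChemFields",
    "binding_site_availability",
    "reaction_terms",
    "reaction_rates_array",
    "cylindrical_laplacian",
    "conserved_totals",
    "species_diffusivities",
]

SPECIES = ("C_C", "C_D", "C_E", "C_X", "C_F0", "C_FC", "C_B0", "C_BC")
_IDX = {name: i for i, name in enumerate(SPECIES)}
#: species transported by diffusion (bound Tcb2 is immobile)
DIFFUSING = ("C_C", "C_D", "C_E", "C_X", "C_F0", "C_FC")


def species_diffusivities(params: ModelParams) -> np.ndarray:
    """Per-species diffusivities in SPECIES order (um^2/s).

    Degraded chelator fragments are assigned the viable-chelator
    diffusivity D_D; bound Tcb2 does not diffuse.
    """
    return np.array([
        params.D_C, params.D_D, params.D_E, params.D_D,
        params.D_T, params.D_T, 0.0, 0.0,
    ])


@dataclass
class ChemFields:
    """The eight chemical concentration fields, stored as one (8, n) array."""

    data: np.ndarray  # shape (8, n_nodes), uM

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(SPECIES):
            raise ValueError(f"expected (8, n) array, got shape {self.data.shape}")

    @classmethod
    def zeros(cls, n_nodes: int) -> "ChemFields":
        return cls(np.zeros((len(SPECIES), n_nodes)))

    @classmethod
    def from_fields(cls, **fields) -> "ChemFields":
        n = len(np.atleast_1d(next(iter(fields.values()))))
        data = np.zeros((len(SPECIES), n))
        for name, values in fields.items():
            data[_IDX[name]] = values
        return cls(data)

    def __getattr__(self, name):
        if name in _IDX:
            return self.data[_IDX[name]]
        raise AttributeError(name)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[_IDX[name]]

    @property
    def C_Btot(self) -> np.ndarray:
        """Total bound Tcb2 density, the C_B used by the mechanics."""
        return self.data[_IDX["C_B0"]] + self.data[_IDX["C_BC"]]

    @property
    def phi(self) -> np.ndarray:
        """Ca-loaded fraction of bound Tcb2 (0 where there is no network)."""
        tot = self.C_Btot
        out = np.zeros_like(tot)
        np.divide(self.data[_IDX["C_BC"]], tot, out=out, where=tot > 0)
        return out

    def copy(self) -> "ChemFields":
        return ChemFields(self.data.copy())


def binding_site_availability(C_Btot, params: ModelParams) -> np.ndarray:
    """Available binding sites S(C) = (sigma0 + C) * max(0, 1 - C/C_sat), in uM.

    Non-monotone in the bound density: new network creates binding sites
    (linear term, with nucleation floor sigma0 at C = 0) while dense network
    sterically blocks them (cutoff at C_sat).  Maximum at (C_sat - sigma0)/2.
    """
    C = np.asarray(C_Btot, dtype=float)
    return (params.sigma0 + C) * np.maximum(0.0, 1.0 - C / params.C_sat)


def reaction_rates_array(y: np.ndarray, light, params: ModelParams) -> np.ndarray:
    """Pointwise reaction rates d(y)/dt (uM/s) for a stacked (8, n) state.

    ``light`` is the local intensity (scalar or per-node array, >= 0).
    This is the hot inner function used by the integrator; the public
    :func:`reaction_terms` wraps it for ChemFields.
    """
    p = params
    C_C, C_D, C_E, C_X, C_F0, C_FC, C_B0, C_BC = y

    J_ph = p.k_ph * light * C_E
    J_chel = p.k_onD * C_D * C_C - p.k_offD * C_E
    J_F = p.k_onT * C_C * C_F0 - p.k_offT * C_FC
    J_B = p.k_onT * C_C * C_B0 - p.k_offT * C_BC
    S = binding_site_availability(C_B0 + C_BC, p)
    J_join0 = p.k_bind0 * S * C_F0
    J_joinC = p.k_bind * S * C_FC
    J_u0 = p.k_u0 * C_B0
    J_uC = p.k_uCa * C_BC

    out = np.empty_like(y)
    out[0] = J_ph - J_chel - J_F - J_B                 # C_C
    out[1] = (1.0 - p.f_deg) * J_ph - J_chel           # C_D
    out[2] = -J_ph + J_chel                            # C_E
    out[3] = p.f_deg * J_ph                            # C_X
    out[4] = -J_F - J_join0 + J_u0                     # C_F0
    out[5] = J_F - J_joinC + J_uC                      # C_FC
    out[6] = -J_B + J_join0 - J_u0                     # C_B0
    out[7] = J_B + J_joinC - J_uC                      # C_BC
    return out


def reaction_terms(chem: ChemFields, light, params: ModelParams) -> ChemFields:
    """Per-species reaction rates (uM/s) at the given light intensity field."""
    light = np.asarray(light, dtype=float)
    if np.any(light < 0):
        raise ValueError("light intensity must be non-negative")
    return ChemFields(reaction_rates_array(chem.data, light, params))


def cylindrical_laplacian(field, grid: RadialGrid) -> np.ndarray:
    """(1/r) d_r (r d_r f) on the radial grid, second order.

    Finite-volume form: regularized at the origin (limit 2 f'' via the
    symmetry condition f(-dr) = f(dr)) and closed with a zero-flux ghost at
    R_max.  Together with the cell weights of ``RadialGrid.node_volumes``
    this conserves the discrete integral of f exactly.

    Works on a single field (n,) or a stack (k, n) along the last axis.
    """
    f = np.asarray(field, dtype=float)
    dr = grid.dr
    r = grid.r
    out = np.empty_like(f)
    # interior: flux differences at half nodes
    r_half = r[:-1] + 0.5 * dr                        # r_{i+1/2}, i = 0..N-1
    flux = r_half * np.diff(f, axis=-1)               # r_{i+1/2} (f_{i+1} - f_i)
    out[..., 1:-1] = (flux[..., 1:] - flux[..., :-1]) / (r[1:-1] * dr * dr)
    # origin: lim (1/r) d_r(r d_r f) = 2 f''(0); with symmetry ghost this is
    # also 2 pi * F_{1/2} / cell volume, so mass telescopes exactly
    out[..., 0] = 4.0 * (f[..., 1] - f[..., 0]) / (dr * dr)
    # outer boundary: no-flux ghost, half cell of area 2 pi * vol_N
    vol_N = 0.5 * (r[-1] ** 2 - (r[-1] - 0.5 * dr) ** 2)
    out[..., -1] = -flux[..., -1] / (vol_N * dr)
    return out


def conserved_totals(chem: ChemFields, grid: RadialGrid) -> dict:
    """Audit of the three conserved pools of the closed (no-flux) system.

    Uses the finite-volume node weights so the result is an exact discrete
    invariant of the diffusion stencil; reactions conserve these sums
    pointwise by stoichiometry.  Units: uM * um^2 (amount per unit height).
    """
    w = grid.node_volumes()
    c = chem
    return {
        "Ca_total": float(w @ (c.C_C + c.C_E + c.C_FC + c.C_BC)),
        "Tcb2_total": float(w @ (c.C_F0 + c.C_FC + c.C_B0 + c.C_BC)),
        "chelator_total": float(w @ (c.C_D + c.C_E + c.C_X)),
    }
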