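"""Grids, model parameters and state containers shared by all modules.

The simulator works on a uniform node-based radial grid including the
origin, with azimuthal symmetry assumed throughout.  Quantities carry the
units used in the rest of the package: lengths in um, time in s,
concentrations in uM, and stress in units of the drag coefficient Gamma
(Gamma = 1 by default, which fixes the stress scale; only ratios of moduli
to drag are physical here).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import simpson

__all__ = [
    "RadialGrid",
    "ModelParams",
    "FieldState",
    "build_grid",
    "radial_integral",
    "validate_params",
    "default_params",
    "params_to_dict",
    "params_from_dict",
]

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class RadialGrid:
    """Uniform radial grid with nodes r_i = i*dr, i = 0..N_r (inclusive).

    Attributes
    ----------
    N_r : number of intervals; the grid has ``N_r + 1`` nodes.
    dr : node spacing (um).
    r : node positions (um); ``r[0] == 0`` exactly and ``r[-1] == R_max``.
    """

    N_r: int
    dr: float
    r: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.r is None:
            object.__setattr__(self, "r", np.arange(self.N_r + 1) * float(self.dr))

    @property
    def R_max(self) -> float:
        return self.N_r * self.dr

    @property
    def n_nodes(self) -> int:
        return self.N_r + 1

    def node_volumes(self) -> np.ndarray:
        """Finite-volume cell areas 2*pi*r_i*dr (um^2) associated with each node.

        These are the exact discrete invariant weights of the no-flux
        cylindrical diffusion stencil: the center cell is the disk
        [0, dr/2], interior cells are annuli [r_i - dr/2, r_i + dr/2], and
        the boundary cell is the half-annulus [R_max - dr/2, R_max].
        """
        dr, r = self.dr, self.r
        v = 2.0 * np.pi * r * dr
        v[0] = np.pi * (dr / 2.0) ** 2
        v[-1] = np.pi * (r[-1] ** 2 - (r[-1] - dr / 2.0) ** 2)
        return v


def build_grid(N_r: int, dr: float) -> RadialGrid:
    """Build a uniform radial grid spanning [0, N_r*dr].

    Raises
    ------
    ValueError
        if ``N_r < 8`` or ``dr <= 0``.
    """
    if not isinstance(N_r, (int, np.integer)) or N_r < 8:
        raise ValueError(f"N_r must be an integer >= 8, got {N_r!r}")
    if dr <= 0:
        raise ValueError(f"dr must be positive, got {dr!r}")
    return RadialGrid(N_r=int(N_r), dr=float(dr))


def radial_integral(field_values, grid: RadialGrid) -> float:
    """Integral of a radial field over the disk, int_0^Rmax f(r) 2 pi r dr.

    Uses Simpson's rule on the node values, which is exact for
    polynomial integrands ``f(r) * r`` up to cubic order (e.g. disk area
    for f = const, and f = r).
    """
    f = np.asarray(field_values, dtype=float)
    if f.shape != grid.r.shape:
        raise ValueError(
            f"field has shape {f.shape}, expected {grid.r.shape} for this grid"
        )
    return float(simpson(2.0 * np.pi * grid.r * f, x=grid.r))


# --- model parameters ------------------------------------------------------

#: fields fixed by physical argument rather than calibration:
#: D_T = 10 um^2/s (monomer size estimate), Gamma = 1 (stress unit), p_stiff = 1.
@dataclass
class ModelParams:
    """Every rate constant, diffusivity, stiffness and drag coefficient.

    Units: diffusivities um^2/s; first-order rates 1/s; second-order rates
    1/(uM s); concentrations uM; moduli in stress units (set by Gamma = 1);
    g_max dimensionless (negative = contraction).
    """

    # diffusivities (um^2/s)
    D_C: float
    D_D: float
    D_E: float
    D_T: float
    # photolysis
    k_ph: float        # 1/(intensity s)
    f_deg: float       # fraction of chelator degraded per photolysis event
    # chelation  D + C <-> E
    k_onD: float       # 1/(uM s)
    k_offD: float      # 1/s
    # Ca-Tcb2 exchange (same on/off in free and bound states)
    k_onT: float       # 1/(uM s)
    k_offT: float      # 1/s
    # network joining/leaving
    k_bind: float      # 1/(uM s), joining of Ca-loaded Tcb2 (FC -> BC)
    k_bind0: float     # 1/(uM s), joining of Ca-free Tcb2 (F0 -> B0); slow,
                       # since the binding interface is exposed by the
                       # Ca-induced conformational change
    k_u0: float        # 1/s, unbinding of Ca-free bound Tcb2
    k_uCa: float       # 1/s, unbinding of Ca-loaded bound Tcb2 (< k_u0)
    # binding-site availability S(C) = (sigma0 + C) max(0, 1 - C/C_sat)
    sigma0: float      # uM
    C_sat: float       # uM
    # mechanics
    mu0: float         # stress / uM^p_stiff
    p_stiff: float
    lambda_ratio: float
    mu_floor: float    # stress
    g_max: float       # dimensionless, <= 0
    Gamma: float       # stress s / um^2
    # conserved pools (uniform initial concentrations, uM)
    C_T_tot: float
    C_D_tot: float
    C_Ca_tot: float

    def D_max(self) -> float:
        return max(self.D_C, self.D_D, self.D_E, self.D_T)


_PARAM_FIELDS = [f.name for f in dataclasses.fields(ModelParams)]


def validate_params(params: ModelParams) -> ModelParams:
    """Check every parameter invariant; return params unchanged if all hold.

    Raises ``ValueError`` naming each violated invariant.
    """
    p = params
    problems = []
    if not p.k_uCa < p.k_u0:
        problems.append(
            f"Ca-stabilization violated: require k_uCa < k_u0 "
            f"(got k_uCa={p.k_uCa}, k_u0={p.k_u0})"
        )
    if not (0.0 <= p.f_deg <= 1.0):
        problems.append(f"f_deg must lie in [0, 1], got {p.f_deg}")
    for name in ("D_C", "D_D", "D_E", "D_T", "k_ph", "k_onD", "k_offD",
                 "k_onT", "k_offT", "k_bind", "k_bind0", "k_u0", "k_uCa",
                 "C_T_tot", "C_D_tot", "C_Ca_tot", "p_stiff", "mu0"):
        if getattr(p, name) < 0:
            problems.append(f"{name} must be >= 0, got {getattr(p, name)}")
    if not p.mu_floor > 0:
        problems.append(f"mu_floor must be > 0, got {p.mu_floor}")
    if not p.Gamma > 0:
        problems.append(f"Gamma must be > 0, got {p.Gamma}")
    if not p.g_max <= 0:
        problems.append(f"g_max must be <= 0 (contraction), got {p.g_max}")
    if not (p.C_sat > p.sigma0 >= 0):
        problems.append(
            f"require C_sat > sigma0 >= 0, got C_sat={p.C_sat}, sigma0={p.sigma0}"
        )
    if p.lambda_ratio < 0:
        problems.append(f"lambda_ratio must be >= 0, got {p.lambda_ratio}")
    if problems:
        raise ValueError("invalid ModelParams:\n  " + "\n  ".join(problems))
    return params


def params_to_dict(params: ModelParams) -> dict:
    """Serialize to a flat dict; every field name appears verbatim as a key."""
    return {name: getattr(params, name) for name in _PARAM_FIELDS}


def params_from_dict(record: dict) -> ModelParams:
    """Build validated ModelParams from a flat mapping (e.g. a parsed TOML table).

    Unknown keys are rejected to catch typos.
    """
    unknown = sorted(set(record) - set(_PARAM_FIELDS))
    if unknown:
        raise ValueError(f"unknown parameter keys: {unknown}")
    missing = sorted(set(_PARAM_FIELDS) - set(record))
    if missing:
        raise ValueError(f"missing parameter keys: {missing}")
    return validate_params(ModelParams(**{k: float(record[k]) for k in _PARAM_FIELDS}))


def default_params() -> ModelParams:
    """The calibrated default parameter set.

    Loaded from the packaged ``data/default_params.toml``, which is written
    by ``scripts/calibrate.py`` (see docs/methods.md for the calibration
    procedure and rationale for each value).
    """
    import tomllib

    with open(_DATA_DIR / "default_params.toml", "rb") as fh:
        record = tomllib.load(fh)
    return params_from_dict(record["params"])


# --- state container -------------------------------------------------------

@dataclass
class FieldState:
    """All chemical and mechanical fields on the radial grid at one time."""

    t: float
    chem: "ChemFields"
    mech: "MechFields"

    def copy(self) -> "FieldState":
        return FieldState(t=self.t, chem=self.chem.copy(), mech=self.mech.copy())
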