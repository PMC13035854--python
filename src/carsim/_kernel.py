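"""Compiled inner loop for the radial integrator.

Mirrors exactly the arithmetic of ``simulate._rhs_radial`` + Heun stepping
(reactions, cylindrical diffusion, variational elastic force, overdamped
velocity) in loop form for numba.  Falls back to the pure-numpy path in
``simulate`` when numba is unavailable; a regression test asserts the two
paths agree.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


# parameter-vector layout (see pack_params)
_P_FIELDS = ("k_ph", "f_deg", "k_onD", "k_offD", "k_onT", "k_offT",
             "k_bind", "k_bind0", "k_u0", "k_uCa", "sigma0", "C_sat",
             "mu0", "p_stiff", "lambda_ratio", "mu_floor", "g_max", "Gamma")


def pack_params(params) -> np.ndarray:
    return np.array([getattr(params, name) for name in _P_FIELDS])


@njit(cache=True)
def _rhs(y, U, L, P, r, dr, D, dy, dU):
    n = y.shape[1]
    (k_ph, f_deg, k_onD, k_offD, k_onT, k_offT, k_bind, k_bind0, k_u0,
     k_uCa, sigma0, C_sat, mu0, p_stiff, lam_ratio, mu_floor, g_max,
     Gamma) = (P[0], P[1], P[2], P[3], P[4], P[5], P[6], P[7], P[8], P[9],
               P[10], P[11], P[12], P[13], P[14], P[15], P[16], P[17])

    # reactions
    for i in range(n):
        C_C = y[0, i]
        C_D = y[1, i]
        C_E = y[2, i]
        C_F0 = y[4, i]
        C_FC = y[5, i]
        C_B0 = y[6, i]
        C_BC = y[7, i]
        J_ph = k_ph * L[i] * C_E
        J_chel = k_onD * C_D * C_C - k_offD * C_E
        J_F = k_onT * C_C * C_F0 - k_offT * C_FC
        J_B = k_onT * C_C * C_B0 - k_offT * C_BC
        CB = C_B0 + C_BC
        S = (sigma0 + CB) * max(0.0, 1.0 - CB / C_sat)
        J_join0 = k_bind0 * S * C_F0
        J_joinC = k_bind * S * C_FC
        J_u0 = k_u0 * C_B0
        J_uC = k_uCa * C_BC
        dy[0, i] = J_ph - J_chel - J_F - J_B
        dy[1, i] = (1.0 - f_deg) * J_ph - J_chel
        dy[2, i] = -J_ph + J_chel
        dy[3, i] = f_deg * J_ph
        dy[4, i] = -J_F - J_join0 + J_u0
        dy[5, i] = J_F - J_joinC + J_uC
        dy[6, i] = -J_B + J_join0 - J_u0
        dy[7, i] = J_B + J_joinC - J_uC

    # diffusion of mobile species (no-flux cylindrical finite volume)
    dr2 = dr * dr
    r_last = r[n - 1]
    volN = 0.5 * (r_last * r_last - (r_last - 0.5 * dr) * (r_last - 0.5 * dr))
    for s in range(6):
        Ds = D[s]
        if Ds == 0.0:
            continue
        dy[s, 0] += Ds * 4.0 * (y[s, 1] - y[s, 0]) / dr2
        prev_flux = (r[0] + 0.5 * dr) * (y[s, 1] - y[s, 0])
        for i in range(1, n - 1):
            flux = (r[i] + 0.5 * dr) * (y[s, i + 1] - y[s, i])
            dy[s, i] += Ds * (flux - prev_flux) / (r[i] * dr2)
            prev_flux = flux
        dy[s, n - 1] += -Ds * prev_flux / (volN * dr)

    # mechanics: variational elastic force, overdamped velocity
    dU[0] = 0.0
    dU[n - 1] = 0.0
    a_prev = 0.0
    for c in range(n - 1):
        CB_l = y[6, c] + y[7, c]
        CB_r = y[6, c + 1] + y[7, c + 1]
        mu_l = mu_floor + mu0 * CB_l ** p_stiff
        mu_r = mu_floor + mu0 * CB_r ** p_stiff
        phi_l = y[7, c] / CB_l if CB_l > 0.0 else 0.0
        phi_r = y[7, c + 1] / CB_r if CB_r > 0.0 else 0.0
        mu_c = 0.5 * (mu_l + mu_r)
        lam_c = lam_ratio * mu_c
        g_c = 0.5 * g_max * (phi_l + phi_r)
        rsum = r[c] + r[c + 1]
        eps_rr = (U[c + 1] - U[c]) / dr
        eps_tt = (U[c] + U[c + 1]) / rsum
        tr = eps_rr + eps_tt - 2.0 * g_c
        sig_rr = lam_c * tr + 2.0 * mu_c * (eps_rr - g_c)
        sig_tt = lam_c * tr + 2.0 * mu_c * (eps_tt - g_c)
        w_c = np.pi * rsum * dr
        a_c = w_c * (sig_rr / dr + sig_tt / rsum)
        b_c = w_c * (-sig_rr / dr + sig_tt / rsum)
        if c >= 1:
            f = -(a_prev + b_c) / (2.0 * np.pi * r[c] * dr)
            dU[c] = f / Gamma
        a_prev = a_c


@njit(cache=True)
def integrate_block(y, U, P, r, dr, D, prof, gate1, gate2, dt):
    """Advance ``len(gate1)`` Heun steps in place.

    gate1[k] / gate2[k] are the light gates at the two stages of step k.
    Returns (status, step, species, node): status 0 = ok, 1 = negative
    concentration, 2 = non-finite value.
    """
    n_species, n = y.shape
    k1y = np.empty((n_species, n))
    k2y = np.empty((n_species, n))
    y_p = np.empty((n_species, n))
    k1U = np.empty(n)
    k2U = np.empty(n)
    U_p = np.empty(n)
    L1 = np.empty(n)
    L2 = np.empty(n)
    n_steps = gate1.shape[0]
    for step in range(n_steps):
        for i in range(n):
            L1[i] = prof[i] * gate1[step]
            L2[i] = prof[i] * gate2[step]
        _rhs(y, U, L1, P, r, dr, D, k1y, k1U)
        for s in range(n_species):
            for i in range(n):
                y_p[s, i] = y[s, i] + dt * k1y[s, i]
        for i in range(n):
            U_p[i] = U[i] + dt * k1U[i]
        U_p[0] = 0.0
        U_p[n - 1] = 0.0
        _rhs(y_p, U_p, L2, P, r, dr, D, k2y, k2U)
        for s in range(n_species):
            for i in range(n):
                y[s, i] += 0.5 * dt * (k1y[s, i] + k2y[s, i])
        for i in range(n):
            U[i] += 0.5 * dt * (k1U[i] + k2U[i])
        U[0] = 0.0
        U[n - 1] = 0.0
        for s in range(n_species):
            for i in range(n):
                v = y[s, i]
                if not np.isfinite(v):
                    return 2, step, s, i
                if v < -1e-9:
                    return 1, step, s, i
    return 0, n_steps, 0, 0
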