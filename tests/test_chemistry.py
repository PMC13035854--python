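"""Reaction network, binding-site availability, and the radial Laplacian."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import carsim as cs
from carsim.chemistry import SPECIES, reaction_rates_array
from conftest import make_fast_params, replace, uniform_chem


class TestBindingSiteAvailability:
    def test_nucleation_floor_at_zero(self, fast_params):
        assert cs.binding_site_availability(0.0, fast_params) == pytest.approx(
            fast_params.sigma0)

    def test_vanishes_at_saturation(self, fast_params):
        p = fast_params
        assert cs.binding_site_availability(p.C_sat, p) == pytest.approx(0.0)
        assert cs.binding_site_availability(2 * p.C_sat, p) == 0.0

    def test_argmax_matches_closed_form(self, fast_params):
        p = fast_params
        C = np.linspace(0, p.C_sat, 200001)
        S = cs.binding_site_availability(C, p)
        argmax_scan = C[np.argmax(S)]  # brute-force oracle
        assert argmax_scan == pytest.approx((p.C_sat - p.sigma0) / 2, abs=0.01)

    def test_nonnegative_everywhere(self, fast_params):
        C = np.linspace(0, 5 * fast_params.C_sat, 1000)
        assert (cs.binding_site_availability(C, fast_params) >= 0).all()


class TestReactionTerms:
    def test_all_zero_state_gives_zero_rates(self, fast_params):
        chem = cs.ChemFields.zeros(5)
        rates = cs.reaction_terms(chem, np.zeros(5), fast_params)
        assert np.all(rates.data == 0.0)

    def test_single_chelation_reaction(self, fast_params):
        p = fast_params
        chem = cs.ChemFields.from_fields(C_D=[1.0], C_C=[1.0])
        rates = cs.reaction_terms(chem, 0.0, p)
        assert rates["C_E"][0] == pytest.approx(p.k_onD)
        assert rates["C_D"][0] == pytest.approx(-p.k_onD)
        assert rates["C_C"][0] == pytest.approx(-p.k_onD)

    def test_photolysis_splits_viable_and_degraded_chelator(self):
        p = make_fast_params(k_offD=0.0)  # isolate the photolysis channel
        chem = cs.ChemFields.from_fields(C_E=[1.0])
        rates = cs.reaction_terms(chem, 1.0, p)
        J = p.k_ph
        assert rates["C_C"][0] == pytest.approx(J)
        assert rates["C_E"][0] == pytest.approx(-J)
        assert rates["C_D"][0] == pytest.approx((1 - p.f_deg) * J)
        assert rates["C_X"][0] == pytest.approx(p.f_deg * J)
        # total chelator is conserved through photolysis bookkeeping
        total = rates["C_D"] + rates["C_E"] + rates["C_X"]
        assert total[0] == pytest.approx(0.0, abs=1e-14)

    def test_negative_light_rejected(self, fast_params):
        with pytest.raises(ValueError, match="light"):
            cs.reaction_terms(cs.ChemFields.zeros(3), -1.0, fast_params)

    @given(data=st.lists(
        st.floats(min_value=0.0, max_value=500.0), min_size=8, max_size=8),
        light=st.floats(min_value=0.0, max_value=2.0))
    @settings(max_examples=50, deadline=None)
    def test_stoichiometric_conservation_pointwise(self, data, light):
        """Every reaction moves mass between exactly two pools, so the Ca,
        Tcb2 and chelator sums have identically zero rate at every point."""
        y = np.array(data)[:, None]
        dy = reaction_rates_array(y, light, make_fast_params())
        idx = {s: i for i, s in enumerate(SPECIES)}
        dCa = sum(dy[idx[s], 0] for s in ("C_C", "C_E", "C_FC", "C_BC"))
        dT = sum(dy[idx[s], 0] for s in ("C_F0", "C_FC", "C_B0", "C_BC"))
        dD = sum(dy[idx[s], 0] for s in ("C_D", "C_E", "C_X"))
        scale = max(1.0, np.abs(dy).max())
        assert abs(dCa) < 1e-10 * scale
        assert abs(dT) < 1e-10 * scale
        assert abs(dD) < 1e-10 * scale


class TestCylindricalLaplacian:
    def test_constant_field_is_harmonic(self, grid):
        lap = cs.cylindrical_laplacian(np.full(grid.n_nodes, 3.7), grid)
        np.testing.assert_allclose(lap, 0.0, atol=1e-12)

    def test_r_squared_gives_four(self, grid):
        lap = cs.cylindrical_laplacian(grid.r**2, grid)
        # exact for the stencil away from the no-flux outer closure
        np.testing.assert_allclose(lap[:-1], 4.0, rtol=1e-12)

    def test_origin_regularization_matches_smooth_limit(self):
        g = cs.build_grid(64, 0.05)
        f = np.cos(g.r)
        lap = cs.cylindrical_laplacian(f, g)
        # at r=0: (1/r)(r f')' -> 2 f''(0) = -2
        assert lap[0] == pytest.approx(-2.0, rel=5e-3)

    def test_gaussian_diffusion_matches_heat_kernel(self):
        """Pure diffusion of a Gaussian follows the 2D heat kernel."""
        D, sigma = 10.0, 5.0
        g = cs.build_grid(256, 0.5)
        tau0 = sigma**2 / (2 * D)
        c = np.exp(-g.r**2 / (4 * D * tau0))
        dt = 0.4 * g.dr**2 / (4 * D)
        T = 10.0
        n = int(round(T / dt))
        for _ in range(n):
            k1 = D * cs.cylindrical_laplacian(c, g)
            k2 = D * cs.cylindrical_laplacian(c + dt * k1, g)
            c = c + 0.5 * dt * (k1 + k2)
        tau = tau0 + n * dt
        exact = (tau0 / tau) * np.exp(-g.r**2 / (4 * D * tau))
        assert np.max(np.abs(c - exact)) / exact.max() < 0.01

    def test_discrete_mass_conservation(self, grid, rng):
        f = rng.uniform(size=grid.n_nodes)
        w = grid.node_volumes()
        assert abs(w @ cs.cylindrical_laplacian(f, grid)) < 1e-10 * (w @ f)


class TestWellMixedLimits:
    def test_chelation_equilibrium_against_ode_oracle(self, fast_params):
        """With no light and no Tcb2 the chelation subsystem relaxes to
        C_E / (C_D C_C) = k_onD / k_offD, matching an independent ODE solve."""
        p = replace(fast_params, C_T_tot=0.0, D_C=0.0, D_D=0.0, D_E=0.0, D_T=0.0)
        grid = cs.build_grid(8, 1.0)
        state = cs.FieldState(
            t=0.0,
            chem=cs.ChemFields.from_fields(
                C_C=np.full(9, 30.0), C_D=np.full(9, 80.0), C_E=np.full(9, 5.0)),
            mech=cs.MechFields.zeros(9))
        proto = cs.LightProtocol(kind="disk_step", A=0.0)

        def ode(_, y):
            c, d, e = y
            J = p.k_onD * d * c - p.k_offD * e
            return [-J, -J, J]

        sol = solve_ivp(ode, (0, 60.0), [30.0, 80.0, 5.0], rtol=1e-10,
                        atol=1e-12)
        dt = cs.stable_dt(p, grid, 0.4)
        t = 0.0
        while t < 60.0:
            state = cs.heun_step(state, t, dt, proto, p, grid)
            t += dt
        c, d, e = state.chem.C_C[0], state.chem.C_D[0], state.chem.C_E[0]
        np.testing.assert_allclose([c, d, e], sol.y[:, -1], rtol=1e-5)
        assert e / (d * c) == pytest.approx(p.k_onD / p.k_offD, rel=1e-3)

    def test_dark_resequestration_monotone(self, fast_params):
        """Switching the light off from a photolyzed state: free Ca2+ decays
        monotonically as the remaining viable chelator resequesters it."""
        p = replace(fast_params, C_T_tot=0.0)
        grid = cs.build_grid(8, 1.0)
        state = cs.FieldState(
            t=0.0,
            chem=cs.ChemFields.from_fields(
                C_C=np.full(9, 60.0), C_D=np.full(9, 140.0),
                C_E=np.full(9, 0.0), C_X=np.full(9, 40.0)),
            mech=cs.MechFields.zeros(9))
        proto = cs.LightProtocol(kind="disk_step", A=0.0)
        dt = cs.stable_dt(p, grid, 0.4)
        cc = [state.chem.C_C[0]]
        for i in range(400):
            state = cs.heun_step(state, i * dt, dt, proto, p, grid)
            cc.append(state.chem.C_C[0])
        cc = np.array(cc)
        assert np.all(np.diff(cc) <= 1e-12)
        eq = p.k_offD / p.k_onD * state.chem.C_E[0] / state.chem.C_D[0]
        assert cc[-1] > eq  # decreasing toward the chelation equilibrium

    def test_photolysis_millisecond_half_life(self, default_params):
        """Under full calibrated illumination the caged complex decays with a
        half-life below 10 ms."""
        p = default_params
        half_life = np.log(2.0) / (p.k_ph * 1.0)
        assert half_life < 0.010


class TestConservedTotals:
    def test_uniform_state_equals_concentration_times_disk_area(self, fast_params):
        grid = cs.build_grid(16, 0.5)
        chem = uniform_chem(fast_params, grid.n_nodes)
        totals = cs.conserved_totals(chem, grid)
        area = np.pi * grid.R_max**2
        p = fast_params
        assert totals["Ca_total"] == pytest.approx(p.C_Ca_tot * area, rel=1e-12)
        assert totals["Tcb2_total"] == pytest.approx(p.C_T_tot * area, rel=1e-12)
        assert totals["chelator_total"] == pytest.approx(p.C_D_tot * area, rel=1e-12)
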