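"""Time integration: step control, Heun accuracy, conservation, 2D mode."""

import dataclasses

import numpy as np
import pytest

import carsim as cs
from carsim.simulate import Grid2D, initial_chem, run_chem2d
from carsim.illumination import disk_mask
from conftest import make_fast_params, replace, uniform_chem


class TestStableDt:
    def test_diffusion_limited_formula(self):
        p = make_fast_params(D_C=100.0, D_D=1.0, D_E=1.0, D_T=1.0,
                             k_ph=1e-3, k_onD=1e-6, k_onT=1e-6, k_offD=1e-6,
                             k_offT=1e-6, k_bind=1e-9, k_bind0=1e-10,
                             k_u0=1e-6, k_uCa=1e-7,
                             mu0=1e-6, mu_floor=1e-6, lambda_ratio=0.0)
        g = cs.build_grid(16, 1.0)
        assert cs.stable_dt(p, g, 0.5) == pytest.approx(0.00125, rel=1e-6)

    def test_zero_diffusion_reaction_limited(self):
        p = make_fast_params(D_C=0.0, D_D=0.0, D_E=0.0, D_T=0.0)
        g = cs.build_grid(16, 1.0)
        dt = cs.stable_dt(p, g, 0.5)
        assert np.isfinite(dt) and dt > 0

    def test_user_cap_respected(self, fast_params):
        g = cs.build_grid(16, 1.0)
        assert cs.stable_dt(fast_params, g, 0.5, dt_cap=1e-6) == 1e-6

    def test_invalid_safety(self, fast_params):
        g = cs.build_grid(16, 1.0)
        with pytest.raises(ValueError):
            cs.stable_dt(fast_params, g, 0.0)


class TestHeunStep:
    def test_scalar_decay_one_step_value(self):
        """Pure exponential decay dc/dt = -c advanced one Heun step with
        dt = 0.1 gives 0.905 (the scheme's closed-form one-step value)."""
        p = make_fast_params(k_ph=1.0, k_onD=0.0, k_offD=0.0, k_onT=0.0,
                             k_offT=1e-6, k_bind=0.0, k_bind0=0.0,
                             D_C=0.0, D_D=0.0, D_E=0.0, D_T=0.0)
        g = cs.build_grid(8, 1.0)
        state = cs.FieldState(
            t=0.0,
            chem=cs.ChemFields.from_fields(C_E=np.ones(9)),
            mech=cs.MechFields.zeros(9))
        proto = cs.LightProtocol(kind="disk_step", A=1.0, rho=100.0, w_s=0.0)
        out = cs.heun_step(state, 0.0, 0.1, proto, p, g)
        np.testing.assert_allclose(out.chem.C_E, 0.905, rtol=1e-12)

    def test_chelation_equilibrium_is_fixed_point(self, fast_params):
        """Uniform state at chelation equilibrium, no light, no Tcb2:
        one step changes nothing beyond round-off."""
        p = replace(fast_params, C_T_tot=0.0)
        g = cs.build_grid(8, 1.0)
        K = p.k_onD / p.k_offD
        n = g.n_nodes
        chem = cs.ChemFields.from_fields(
            C_C=np.full(n, 2.0), C_D=np.full(n, 10.0),
            C_E=np.full(n, K * 20.0))
        state = cs.FieldState(t=0.0, chem=chem, mech=cs.MechFields.zeros(n))
        proto = cs.LightProtocol(kind="disk_step", A=0.0)
        out = cs.heun_step(state, 0.0, 1e-3, proto, p, g)
        np.testing.assert_allclose(out.chem.data, state.chem.data, rtol=1e-12)

    def test_negative_state_detected_and_named(self, fast_params):
        g = cs.build_grid(8, 1.0)
        chem = cs.ChemFields.zeros(g.n_nodes)
        chem.data[0, 3] = -1.0
        state = cs.FieldState(t=0.0, chem=chem, mech=cs.MechFields.zeros(9))
        proto = cs.LightProtocol(kind="disk_step", A=0.0)
        with pytest.raises(cs.IntegrationError, match="C_C"):
            cs.heun_step(state, 0.0, 1e-3, proto, fast_params, g)


def tiny_run_config(params, duration=2.0, A=1.0, save_every=0.5, N=24, dr=2.0,
                    **proto_kw):
    grid = cs.build_grid(N, dr)
    proto = cs.LightProtocol(kind="disk_step", A=A, rho=0.4 * grid.R_max,
                             w_s=dr, **proto_kw)
    return cs.RunConfig(grid=grid, params=params, protocol=proto,
                        duration=duration, save_every=save_every)


class TestRunSimulation:
    def test_zero_amplitude_stays_dark_and_still(self, fast_params):
        cfg = tiny_run_config(fast_params, A=0.0, duration=3.0)
        traj = cs.run_simulation(cfg)
        # only the negligible dark-nucleation floor, far below any
        # detection threshold (default detection: 5% of C_sat)
        assert traj.field_frames("C_Btot").max() < 1e-3 * fast_params.C_sat
        assert np.abs(traj.U).max() < 1e-12

    def test_illumination_radius_must_fit_grid(self, fast_params):
        grid = cs.build_grid(16, 1.0)
        proto = cs.LightProtocol(kind="disk_step", A=1.0, rho=20.0)
        cfg = cs.RunConfig(grid=grid, params=fast_params, protocol=proto,
                           duration=1.0, save_every=0.5)
        with pytest.raises(ValueError, match="R_max"):
            cs.run_simulation(cfg)

    def test_save_times_strictly_increasing_and_deterministic(self,
                                                              fast_params):
        cfg = tiny_run_config(fast_params, duration=2.0, save_every=0.5)
        t1 = cs.run_simulation(cfg)
        t2 = cs.run_simulation(cfg)
        assert (np.diff(t1.times) > 0).all()
        np.testing.assert_array_equal(t1.chem, t2.chem)
        np.testing.assert_array_equal(t1.U, t2.U)

    def test_conservation_along_trajectory(self, fast_params):
        cfg = tiny_run_config(fast_params, duration=3.0, save_every=0.5)
        traj = cs.run_simulation(cfg)
        grid = traj.grid
        t0 = cs.conserved_totals(cs.ChemFields(traj.chem[0]), grid)
        for frame in traj.chem[1:]:
            tn = cs.conserved_totals(cs.ChemFields(frame), grid)
            for key in t0:
                assert tn[key] == pytest.approx(t0[key], rel=1e-9)

    def test_nonnegativity_over_random_parameter_draws(self):
        """The stability-limited step keeps every concentration
        non-negative (no clipping anywhere in the integrator)."""
        rng = np.random.default_rng(42)
        for _ in range(6):
            p = make_fast_params(
                D_C=10 ** rng.uniform(0, 2), D_D=10 ** rng.uniform(0, 2),
                D_E=10 ** rng.uniform(0, 2), D_T=10 ** rng.uniform(-1, 1),
                k_ph=10 ** rng.uniform(0, 2), f_deg=rng.uniform(0, 1),
                k_onD=10 ** rng.uniform(-3, -1.5),
                k_offD=10 ** rng.uniform(-4, -1),
                k_onT=10 ** rng.uniform(-3, -1.5),
                k_offT=10 ** rng.uniform(-1, 0.5),
                k_bind=10 ** rng.uniform(-3, -2), k_bind0=1e-5,
                k_u0=10 ** rng.uniform(-2, -1),
                k_uCa=10 ** rng.uniform(-4, -2.5))
            cfg = tiny_run_config(p, duration=1.0, save_every=0.25)
            traj = cs.run_simulation(cfg)  # raises IntegrationError on negatives
            assert traj.chem.min() >= -1e-9

    def test_network_confined_before_spreading(self, default_params):
        """Short continuous run: the bound network appears inside the disk
        and the radius is non-decreasing while the light is on."""
        grid = cs.build_grid(48, 3.0)
        proto = cs.LightProtocol(kind="disk_step", A=1.0, rho=37.5, w_s=3.0)
        cfg = cs.RunConfig(grid=grid, params=default_params, protocol=proto,
                           duration=6.0, save_every=1.0)
        traj = cs.run_simulation(cfg)
        CB = traj.field_frames("C_Btot")
        assert CB[-1][:10].min() > 10 * CB[-1][-5:].max()
        radii = [cs.network_radius(c, grid, 0.05 * default_params.C_sat)
                 for c in CB]
        assert (np.diff(radii) >= -grid.dr).all()


class TestHeunConvergence:
    def test_second_order_on_smooth_coupled_run(self, fast_params):
        """Richardson dt-halving on a short smooth run: global error drops
        about 4x per halving (observed order ~2)."""
        grid = cs.build_grid(16, 2.0)
        proto = cs.LightProtocol(kind="disk_step", A=1.0, rho=12.0, w_s=4.0)

        def run(dt):
            p = fast_params
            from carsim.chemistry import species_diffusivities
            from carsim.simulate import _rhs_radial

            D = species_diffusivities(p)
            prof = proto.radial_profile(grid.r)
            y = initial_chem(p, grid.n_nodes)
            U = np.zeros(grid.n_nodes)
            n = int(round(1.0 / dt))
            for _ in range(n):
                k1y, k1U = _rhs_radial(y, U, prof, p, grid, D)
                y_p, U_p = y + dt * k1y, U + dt * k1U
                k2y, k2U = _rhs_radial(y_p, U_p, prof, p, grid, D)
                y = y + 0.5 * dt * (k1y + k2y)
                U = U + 0.5 * dt * (k1U + k2U)
                U[0] = U[-1] = 0.0
            return y

        dt0 = cs.stable_dt(fast_params, grid, 0.4)
        dt0 = 1.0 / int(round(1.0 / dt0))
        ref = run(dt0 / 32)
        e1 = np.abs(run(dt0) - ref).max()
        e2 = np.abs(run(dt0 / 2) - ref).max()
        order = np.log2(e1 / e2)
        assert order == pytest.approx(2.0, abs=0.2)


class TestCompiledKernel:
    def test_kernel_matches_numpy_path_to_roundoff(self, fast_params):
        """The compiled integrator loop and the vectorized numpy path
        implement identical arithmetic."""
        import carsim._kernel as kernel

        if not kernel.HAVE_NUMBA:
            # single-path environment: nothing to cross-check
            return
        cfg = tiny_run_config(fast_params, duration=1.0, save_every=0.25)
        t_fast = cs.run_simulation(cfg)
        kernel.HAVE_NUMBA = False
        try:
            t_ref = cs.run_simulation(cfg)
        finally:
            kernel.HAVE_NUMBA = True
        scale = np.abs(t_ref.chem).max()
        assert np.abs(t_fast.chem - t_ref.chem).max() < 1e-12 * scale
        assert np.abs(t_fast.U - t_ref.U).max() < 1e-12


class TestChem2D:
    def test_zero_mask_no_network(self, fast_params):
        g2 = Grid2D(n=24, dx=3.0)
        proto = cs.LightProtocol(kind="mask2d", A=1.0,
                                 mask=np.zeros((24, 24)))
        traj = run_chem2d(proto, fast_params, g2, duration=1.0,
                          save_every=0.5)
        assert traj.field_frames("C_Btot").max() < 1e-3 * fast_params.C_sat

    def test_mask_shape_must_match_grid(self, fast_params):
        g2 = Grid2D(n=24, dx=3.0)
        proto = cs.LightProtocol(kind="mask2d", A=1.0,
                                 mask=np.ones((16, 16)))
        with pytest.raises(ValueError, match="mask"):
            run_chem2d(proto, fast_params, g2, duration=0.1, save_every=0.1)

    def test_pattern_confined_to_star_mask(self, default_params):
        """A star-shaped mask produces a matching bound-Tcb2 pattern within
        a second of light onset."""
        n, dx = 48, 3.0
        xy = (np.arange(n) - (n - 1) / 2.0) * dx
        X, Y = np.meshgrid(xy, xy)
        theta = np.arctan2(Y, X)
        R = np.hypot(X, Y)
        star = (R < 30.0 + 18.0 * np.cos(5 * theta)).astype(float)
        proto = cs.LightProtocol(kind="mask2d", A=1.0, mask=star)
        traj = run_chem2d(proto, default_params, Grid2D(n=n, dx=dx),
                          duration=1.0, save_every=0.5)
        CB = traj.field_frames("C_Btot")[-1]
        inside = CB[star > 0.5].mean()
        outside = CB[(star < 0.5) & (R > 70.0)].mean()
        assert inside > 20 * max(outside, 1e-12)

    def test_disk_mask_matches_radial_solver(self, default_params):
        """Azimuthally averaged 2D chemistry on a disk agrees with the 1D
        radial solver within 2% RMS."""
        n, dx = 96, 2.0
        g2 = Grid2D(n=n, dx=dx)
        proto = cs.LightProtocol(kind="disk_step", A=1.0, rho=30.0, w_s=4.0)
        dt_cap = min(cs.stable_dt(default_params, g2, 0.4),
                     cs.stable_dt(default_params, cs.build_grid(48, dx), 0.4))
        traj2 = run_chem2d(proto, default_params, g2, duration=1.0,
                           save_every=1.0, dt_cap=dt_cap)
        p1d = dataclasses.replace(default_params, mu0=1e-6, g_max=0.0)
        g1 = cs.build_grid(48, dx)
        cfg = cs.RunConfig(grid=g1, params=p1d, protocol=proto, duration=1.0,
                           save_every=1.0, dt_cap=dt_cap)
        traj1 = cs.run_simulation(cfg)
        CB2 = traj2.field_frames("C_Btot")[-1]
        CB1 = traj1.field_frames("C_Btot")[-1]
        R = g2.radii()
        azi, ref = [], []
        for j, r in enumerate(g1.r[:40]):
            sel = (R >= r - dx / 2) & (R < r + dx / 2)
            if sel.any():
                azi.append(CB2[sel].mean())
                ref.append(CB1[j])
        azi, ref = np.array(azi), np.array(ref)
        rms = np.sqrt(np.mean((azi - ref) ** 2)) / np.sqrt(np.mean(ref ** 2))
        assert rms < 0.02


class TestTimescaleSeparation:
    def test_mechanics_resets_much_faster_than_network_dissolves(
            self, default_params):
        """After a light flash ends, the displacement recovers with a 1/e
        time at least 5x shorter than the bound-network decay (the
        separation that makes pulsed recharging possible)."""
        grid = cs.build_grid(48, 3.0)
        proto = cs.LightProtocol(kind="disk_step", A=1.0, rho=37.5, w_s=3.0,
                                 t_on=1.0)
        cfg = cs.RunConfig(grid=grid, params=default_params, protocol=proto,
                           duration=240.0, save_every=0.5)
        traj = cs.run_simulation(cfg)
        ts = traj.times
        CB = traj.field_frames("C_Btot").sum(axis=1)
        U = traj.field_frames("U_r")

        def tau_from_peak(series):
            """1/e relaxation time of a transient, measured from its peak."""
            i_pk = int(np.argmax(series))
            s_inf = series[-1]
            target = s_inf + (series[i_pk] - s_inf) / np.e
            below = np.nonzero(series[i_pk:] < target)[0]
            return ts[i_pk + below[0]] - ts[i_pk] if below.size else np.inf

        amp = np.abs(U - U[-1]).max(axis=1)
        tau_mech = tau_from_peak(amp)
        tau_chem = tau_from_peak(CB)
        assert np.isfinite(tau_mech)
        assert tau_chem / tau_mech > 5.0
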