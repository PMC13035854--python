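import dataclasses

import numpy as np
import pytest

import carsim as cs


@pytest.fixture(scope="session")
def default_params():
    return cs.default_params()


@pytest.fixture
def grid():
    """Small grid for unit tests."""
    return cs.build_grid(32, 1.0)


@pytest.fixture
def grid_fine():
    return cs.build_grid(256, 0.5)


def make_fast_params(**overrides):
    """Light-weight, physically valid parameter set for cheap unit tests."""
    base = dict(
        D_C=10.0, D_D=5.0, D_E=5.0, D_T=2.0,
        k_ph=10.0, f_deg=0.4,
        k_onD=0.01, k_offD=0.01,
        k_onT=0.01, k_offT=0.5,
        k_bind=0.01, k_bind0=1e-5, k_u0=0.1, k_uCa=0.01,
        sigma0=2.0, C_sat=100.0,
        mu0=0.1, p_stiff=1.0, lambda_ratio=1.0, mu_floor=0.05,
        g_max=-0.1, Gamma=1.0,
        C_T_tot=50.0, C_D_tot=200.0, C_Ca_tot=100.0,
    )
    base.update(overrides)
    return cs.validate_params(cs.ModelParams(**base))


@pytest.fixture
def fast_params():
    return make_fast_params()


def uniform_chem(params, n_nodes):
    """Uniform initial chemical state as a ChemFields."""
    from carsim.simulate import initial_chem

    return cs.ChemFields(initial_chem(params, n_nodes))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def replace(params, **kw):
    return dataclasses.replace(params, **kw)
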