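"""Shared fixtures: default bean setups, sphere oracle data, heavy runs.

Session-scoped fixtures cache the expensive transient simulations so the
physics tests and the acceptance tests share one set of runs.
"""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from cocoadry import geometry as G
from cocoadry import properties as P
from cocoadry import transport as T


# ---------------------------------------------------------------------------
# independent analytic oracle: diffusion in a sphere with a Robin boundary
# ---------------------------------------------------------------------------

def sphere_mean_series(Bi: float, Fo, n_terms: int = 60) -> np.ndarray:
    """Normalized volume-mean of transient diffusion in a unit sphere.

    Initial value 1, far-field 0, surface condition -du/dr = Bi*u at r=1.
    Eigenvalues mu_n solve mu cos(mu) = (1 - Bi) sin(mu); expansion
    coefficients are obtained by numerical quadrature so this oracle shares
    no code with the finite-element solver it checks.
    """
    mus = [
        brentq(
            lambda mu: mu * np.cos(mu) - (1 - Bi) * np.sin(mu),
            (n - 1) * np.pi + 1e-9,
            n * np.pi - 1e-9,
            xtol=1e-14,
        )
        for n in range(1, n_terms + 1)
    ]
    Fo = np.asarray(Fo, float)
    out = np.zeros_like(Fo)
    for mu in mus:
        phi = lambda x: np.sin(mu * x) / x
        num = quad(lambda x: phi(x) * x * x, 0, 1, limit=200)[0]
        den = quad(lambda x: phi(x) ** 2 * x * x, 0, 1, limit=200)[0]
        out += (num / den) * 3 * num * np.exp(-mu * mu * Fo)
    return out


# ---------------------------------------------------------------------------
# geometry / materials building blocks
# ---------------------------------------------------------------------------

SPHERE_R = 0.006
UNIFORM_RHO, UNIFORM_CP, UNIFORM_K = 1100.0, 3.0, 0.5
CONST_DEFF = 8.6e-10


@pytest.fixture(scope="session")
def bean_geometry():
    return G.build_geometry()


@pytest.fixture(scope="session")
def coarse_bean_mesh(bean_geometry):
    return G.generate_mesh(bean_geometry, target_size=8e-4, shell_layers=2)


@pytest.fixture(scope="session")
def default_mats():
    return T.default_materials()


def sphere_setup(target_size=4e-4, shell_layers=3, hm=1e-5, h=36.0,
                 latent_heat=0.0):
    """Uniform-property sphere with constant diffusivity (oracle case)."""
    geom = G.build_geometry(2 * SPHERE_R, 2 * SPHERE_R, 0.00055)
    mesh = G.generate_mesh(geom, target_size, shell_layers)
    mat = T.TissueMaterial.uniform("uniform", UNIFORM_RHO, UNIFORM_CP, UNIFORM_K)
    mats = {"core": mat, "shell": mat}
    bc = T.BoundaryConditions(
        air=P.AirState(temperature=50.0),
        h=h,
        hm=hm,
        c_inf=0.9,
        latent_heat=latent_heat,
        vapor_limited=False,
    )
    ic = T.InitialConditions(To=24.0, co=10_878.0)
    arr = P.ArrheniusDiffusivity(Do=CONST_DEFF, Ea=0.0)
    return mesh, mats, bc, ic, arr


@pytest.fixture(scope="session")
def sphere_oracle_errors():
    """Max deviation (fraction of span) of c and T volume means vs series."""
    mesh, mats, bc, ic, arr = sphere_setup()
    cfg = T.SolverConfig(dt=2.0, t_end=3600.0, store_snapshots=False)
    res = T.run(mesh, mats, bc, ic, cfg, diffusivity=arr)
    t = res.times[1:]
    mask = t >= 300.0  # compare after 5 min of model time
    th_c = (res.c_mean[1:] - bc.c_inf) / (ic.co - bc.c_inf)
    an_c = sphere_mean_series(bc.hm * SPHERE_R / CONST_DEFF, CONST_DEFF * t / SPHERE_R**2)
    alpha = UNIFORM_K / (UNIFORM_RHO * UNIFORM_CP * 1e3)
    th_T = (res.T_mean[1:] - bc.air.temperature) / (ic.To - bc.air.temperature)
    an_T = sphere_mean_series(bc.h * SPHERE_R / UNIFORM_K, alpha * t / SPHERE_R**2)
    return {
        "c": float(np.abs(th_c - an_c)[mask].max()),
        "T": float(np.abs(th_T - an_T)[mask].max()),
        "result": res,
    }


@pytest.fixture(scope="session")
def sphere_spatial_errors():
    """Volume-mean concentration error vs the series under mesh refinement."""
    sizes = (1.2e-3, 6e-4, 3e-4)
    errors = []
    for size in sizes:
        mesh, mats, bc, ic, arr = sphere_setup(target_size=size, shell_layers=2)
        cfg = T.SolverConfig(dt=1.0, t_end=1800.0, store_snapshots=False,
                             trace_cadence=1800.0)
        res = T.run(mesh, mats, bc, ic, cfg, diffusivity=arr)
        th = (res.c_mean[-1] - bc.c_inf) / (ic.co - bc.c_inf)
        exact = sphere_mean_series(
            bc.hm * SPHERE_R / CONST_DEFF, np.array([CONST_DEFF * 1800.0 / SPHERE_R**2])
        )[0]
        errors.append(abs(th - exact))
    return sizes, errors


# ---------------------------------------------------------------------------
# full-length reference simulations (shared with the acceptance tests)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def four_default_sims(bean_geometry, default_mats):
    """350-min drying runs at 40/50/60/70 °C with default configuration."""
    mesh = G.generate_mesh(bean_geometry, target_size=5e-4, shell_layers=3)
    ic = T.InitialConditions()
    out = {}
    for Tair in (40.0, 50.0, 60.0, 70.0):
        air = P.AirState(temperature=Tair, speed=1.0)
        bc = T.BoundaryConditions.from_air(air, bean_geometry, ic, default_mats)
        cfg = T.SolverConfig(store_snapshots=False)
        out[Tair] = T.run(mesh, default_mats, bc, ic, cfg)
    return out


@pytest.fixture(scope="session")
def bean_short_run(bean_geometry, coarse_bean_mesh, default_mats):
    """Coarse 40-min run at 50 °C for qualitative bean physics checks."""
    ic = T.InitialConditions()
    air = P.AirState(temperature=50.0, speed=1.0)
    bc = T.BoundaryConditions.from_air(air, bean_geometry, ic, default_mats)
    cfg = T.SolverConfig(dt=10.0, t_end=2400.0, store_snapshots=False)
    return T.run(coarse_bean_mesh, default_mats, bc, ic, cfg)
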