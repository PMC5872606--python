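"""Shared fixtures: geometries, coarse grids, synthetic flow fields."""

import numpy as np
import pytest
from hypothesis import settings

from stenoflow.geometry import StenosisGeometry
from stenoflow.grid import generate_grid
from stenoflow.oracles import poiseuille
from stenoflow.rheology import RheologyModel
from stenoflow.solver import BoundaryConditions, FlowField, NumericsConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

R_REF = 5e-3
Q_REF = 0.465e-3 / 60.0


@pytest.fixture(scope="session")
def geom_straight():
    return StenosisGeometry.from_degree(R_REF, 0.0, 4 * R_REF, -6 * R_REF, 30 * R_REF)


@pytest.fixture(scope="session")
def geom_severe():
    return StenosisGeometry.from_degree(R_REF, 0.75, 4 * R_REF, -6 * R_REF, 30 * R_REF)


@pytest.fixture(scope="session")
def grid_straight_small(geom_straight):
    return generate_grid(geom_straight, 96, 20)


@pytest.fixture(scope="session")
def bc_ref():
    return BoundaryConditions(Q=Q_REF, rho=1050.0)


@pytest.fixture(scope="session")
def cfg_fast():
    return NumericsConfig(max_iter=800)


def make_poiseuille_field(grid, mu=0.00345, Q=Q_REF, rho=1050.0, converged=True):
    """Synthetic converged FlowField holding the exact Poiseuille solution."""
    sol = poiseuille(grid.geom.R, Q, mu)
    u = sol.u_of_r(grid.rc)
    v = np.zeros_like(u)
    p = sol.dpdx * (grid.xc - grid.x_faces[-1])
    gpx = np.full_like(u, sol.dpdx)
    gpr = np.zeros_like(u)
    bc = BoundaryConditions(Q=Q, rho=rho)
    uf = np.zeros((grid.nx + 1, grid.nr))
    return FlowField(
        grid=grid,
        rheology=RheologyModel.newtonian(mu),
        bc=bc,
        u=u,
        v=v,
        p=p,
        mu_eff=np.full_like(u, mu),
        Fx=uf,
        Fr=np.zeros((grid.nx, grid.nr + 1)),
        grad_p=(gpx, gpr),
        residual_history=np.zeros((1, 4)),
        converged=converged,
        n_iter=1,
    )


@pytest.fixture()
def poiseuille_field(grid_straight_small):
    return make_poiseuille_field(grid_straight_small)
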