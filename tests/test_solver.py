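"""SIMPLE solver verification against developed-flow solutions.

Straight-tube (eta = 0) cases have exact/semi-analytic references; they
exercise the full discretization (axisymmetric metrics, Rhie-Chow
coupling, boundary conditions) without the cost of a separated flow.
"""

import numpy as np
import pytest

from stenoflow.errors import ConvergenceError
from stenoflow.grid import generate_grid
from stenoflow.oracles import developed_gn_pipe_flow, poiseuille
from stenoflow.rheology import CARREAU_BLOOD, NEWTONIAN_BLOOD, RheologyModel, shear_rate, viscosity
from stenoflow.solver import (
    BoundaryConditions,
    NumericsConfig,
    SimpleSolver,
    momentum_assembly,
    solve_steady,
)

from conftest import Q_REF, R_REF

MU = 0.00345


def l2_error(grid, u, u_exact):
    return float(np.sqrt(np.sum((u - u_exact) ** 2 * grid.vol)
                         / np.sum(u_exact**2 * grid.vol)))


@pytest.fixture(scope="module")
def newt_straight(grid_straight_small, bc_ref, cfg_fast):
    return solve_steady(grid_straight_small, NEWTONIAN_BLOOD, bc_ref, cfg_fast)


@pytest.fixture(scope="module")
def carr_straight(grid_straight_small, bc_ref, cfg_fast):
    return solve_steady(grid_straight_small, CARREAU_BLOOD, bc_ref, cfg_fast)


class TestStraightTubeNewtonian:
    def test_matches_poiseuille_within_1_percent(self, newt_straight):
        g = newt_straight.grid
        ref = poiseuille(R_REF, Q_REF, MU)
        assert l2_error(g, newt_straight.u, ref.u_of_r(g.rc)) < 0.01

    def test_centerline_velocity(self, newt_straight):
        # cell centers sit slightly off-axis; compare against the exact
        # profile evaluated there, and the 2*Um value within a cell width
        assert newt_straight.u[:, 0].max() == pytest.approx(2.0 * 0.09868, rel=5e-3)

    def test_mass_conservation_every_station(self, newt_straight):
        q = newt_straight.flux_profile()
        assert np.abs(q - Q_REF).max() / Q_REF < 1e-3

    def test_no_slip_and_axis_symmetry(self, newt_straight):
        Um = 0.09868
        # wall-adjacent tangential velocity is small (cell center near wall)
        assert np.abs(newt_straight.u[:, -1]).max() < 0.05 * Um
        # axis: radial velocity vanishes
        assert np.abs(newt_straight.v[:, 0]).max() < 1e-3 * Um
        # du/dr -> 0 at the axis: the slope between the first two cell rows
        # is far below the wall shear rate 4 Um / R
        g = newt_straight.grid
        slope = np.abs(newt_straight.u[:, 1] - newt_straight.u[:, 0]) / (
            g.rc[:, 1] - g.rc[:, 0]
        )
        assert slope.max() < 0.2 * 4.0 * Um / R_REF

    def test_converged_flag_and_history(self, newt_straight):
        assert newt_straight.converged
        h = newt_straight.residual_history
        assert h.shape[1] == 4
        assert h[-1, 1] < 1e-6 and h[-1, 2] < 1e-6 and h[-1, 3] < 1e-6


class TestStraightTubeCarreau:
    def test_matches_gn_oracle_within_1_percent(self, carr_straight):
        g = carr_straight.grid
        ref = developed_gn_pipe_flow(R_REF, Q_REF, CARREAU_BLOOD)
        assert l2_error(g, carr_straight.u, ref.u_of_r(g.rc)) < 0.01

    def test_viscosity_fixed_point_consistency(self, carr_straight):
        s = SimpleSolver(carr_straight.grid, CARREAU_BLOOD, carr_straight.bc)
        s.set_field(u=carr_straight.u, v=carr_straight.v, p=carr_straight.p)
        gux, gur, gvx, gvr = s.velocity_gradients()
        gdot = shear_rate(gux, gur, gvx, gvr, carr_straight.v, carr_straight.grid.rc)
        mu_check = viscosity(CARREAU_BLOOD, gdot)
        assert np.abs(carr_straight.mu_eff - mu_check).max() <= 1e-6

    def test_carreau_degenerate_limit_matches_newtonian(
        self, grid_straight_small, bc_ref, cfg_fast
    ):
        # lambda = 0 with mu_0 = 0.00345 is a Newtonian fluid of that viscosity
        degen = RheologyModel.carreau(mu_inf=1e-3, mu_0=MU, lambda_t=0.0)
        f_degen = solve_steady(grid_straight_small, degen, bc_ref, cfg_fast)
        f_newt = solve_steady(grid_straight_small, RheologyModel.newtonian(MU),
                              bc_ref, cfg_fast)
        assert np.abs(f_degen.u - f_newt.u).max() < 1e-5 * f_newt.u.max()


class TestOrderOfAccuracy:
    def test_l2_error_drops_by_at_least_factor_3(self, geom_straight, bc_ref, cfg_fast):
        ref = poiseuille(R_REF, Q_REF, MU)
        errs = []
        for n in ((48, 10), (96, 20)):
            grid = generate_grid(geom_straight, *n)
            f = solve_steady(grid, NEWTONIAN_BLOOD, bc_ref, cfg_fast)
            errs.append(l2_error(grid, f.u, ref.u_of_r(grid.rc)))
        assert errs[0] / errs[1] >= 3.0


class TestDeterminism:
    def test_identical_config_bit_identical_results(self, geom_straight, bc_ref):
        cfg = NumericsConfig(max_iter=400)
        grid = generate_grid(geom_straight, 48, 10)
        f1 = solve_steady(grid, NEWTONIAN_BLOOD, bc_ref, cfg)
        f2 = solve_steady(grid, NEWTONIAN_BLOOD, bc_ref, cfg)
        assert np.array_equal(f1.residual_history, f2.residual_history)
        assert np.array_equal(f1.u, f2.u)
        assert np.array_equal(f1.p, f2.p)


class TestMomentumAssembly:
    def test_system_dimensions_match_cell_count(self, grid_straight_small, bc_ref):
        A_u, b_u, A_v, b_v = momentum_assembly(
            grid_straight_small, NEWTONIAN_BLOOD, bc_ref
        )
        n = grid_straight_small.n_cells
        assert A_u.shape == (n, n) and A_v.shape == (n, n)
        assert b_u.shape == (n,) and b_v.shape == (n,)

    def test_uniform_flow_zero_interior_residual(self, geom_straight):
        # a constant velocity field with uniform viscosity balances
        # convection and diffusion exactly away from the no-slip wall
        grid = generate_grid(geom_straight, 48, 10)
        bc = BoundaryConditions(Q=Q_REF, rho=1050.0, inlet_profile="uniform")
        Um = bc.mean_velocity(R_REF)
        u = np.full((grid.nx, grid.nr), Um)
        v = np.zeros_like(u)
        p = np.zeros_like(u)
        A_u, b_u, _, b_v = momentum_assembly(
            grid, NEWTONIAN_BLOOD, bc, u=u, v=v, p=p
        )
        res = (b_u - A_u @ u.ravel()).reshape(grid.nx, grid.nr)
        scale = 1050.0 * Um * Q_REF / (2 * np.pi)
        assert np.abs(res[:, :-1]).max() < 1e-10 * scale

    def test_poiseuille_is_discrete_interior_solution(self, geom_straight, bc_ref):
        # the exact parabola with its exact linear pressure is an *exact*
        # discrete solution away from the boundaries on a uniform grid
        # (quadratic profiles are differenced exactly); the remaining
        # truncation error lives in the wall row (one-sided gradient) and
        # the inlet/outlet columns, and shrinks under refinement
        from stenoflow.grid import GridClustering

        uniform = GridClustering(radial_beta=0.0, stenosis_refine=1.0,
                                 wake_refine=1.0)
        ref = poiseuille(R_REF, Q_REF, MU)
        norm = 1050.0 * 0.09868 * Q_REF / (2 * np.pi)
        totals = []
        for n in ((40, 10), (80, 20)):
            grid = generate_grid(geom_straight, *n, uniform)
            u = ref.u_of_r(grid.rc)
            v = np.zeros_like(u)
            p = ref.dpdx * (grid.xc - grid.x_faces[-1])
            A_u, b_u, _, _ = momentum_assembly(
                grid, NEWTONIAN_BLOOD, bc_ref, u=u, v=v, p=p
            )
            res = np.abs(b_u - A_u @ u.ravel()).reshape(grid.nx, grid.nr)
            assert res[2:-2, :-1].max() < 1e-12 * norm
            totals.append(res.sum() / norm)
        assert totals[0] / totals[1] >= 1.8


class TestPressureCorrection:
    def test_correction_enforces_discrete_continuity(self, grid_straight_small, bc_ref):
        # after one pressure-correction step the corrected fluxes satisfy
        # continuity to the linear-solver tolerance in every cell
        cfg = NumericsConfig(max_iter=3, raise_on_fail=False)
        s = SimpleSolver(grid_straight_small, NEWTONIAN_BLOOD, bc_ref, cfg)
        s.iterate(max_iter=1)
        defect = s.Fx[1:, :] - s.Fx[:-1, :] + s.Fr[:, 1:] - s.Fr[:, :-1]
        assert np.abs(defect).sum() / (1050.0 * Q_REF / (2 * np.pi)) < 1e-10

    def test_mass_imbalance_reduced_from_uniform_start(self, geom_straight):
        grid = generate_grid(geom_straight, 48, 10)
        bc = BoundaryConditions(Q=Q_REF, rho=1050.0, inlet_profile="uniform")
        cfg = NumericsConfig(max_iter=6, raise_on_fail=False)
        f = solve_steady(grid, NEWTONIAN_BLOOD, bc, cfg)
        h = f.residual_history
        assert h[-1, 1] < h[1, 1]

    def test_divergence_free_fluxes_need_no_correction(self, grid_straight_small, bc_ref):
        # exactly conservative face fluxes give a zero pressure correction
        # and leave the velocity field untouched
        cfg = NumericsConfig(max_iter=10, raise_on_fail=False)
        s = SimpleSolver(grid_straight_small, NEWTONIAN_BLOOD, bc_ref, cfg)
        s._update_viscosity(relax=1.0)
        _, _, _, _, diag_u, _ = s.momentum_assembly()
        s._rAU = s.vol / (diag_u / cfg.relax_u)
        s._rhie_chow_fluxes(s._rAU)         # sets the p' coupling coefficients
        # overwrite with column-constant fluxes: discretely divergence-free
        s.Fx[:] = s.Fx[0, :][None, :]
        s.Fr[:] = 0.0
        u_before, p_before = s.u.copy(), s.p.copy()
        mass_res = s.pressure_correction()
        assert mass_res < 1e-12
        assert np.abs(s.u - u_before).max() < 1e-12 * u_before.max()
        assert np.abs(s.p - p_before).max() < 1e-12


class TestFailureModes:
    def test_nonconvergence_raises_with_history(self, geom_straight, bc_ref):
        grid = generate_grid(geom_straight, 48, 10)
        bc = BoundaryConditions(Q=Q_REF, rho=1050.0, inlet_profile="uniform")
        cfg = NumericsConfig(max_iter=3)
        with pytest.raises(ConvergenceError) as exc:
            solve_steady(grid, NEWTONIAN_BLOOD, bc, cfg)
        assert exc.value.residual_history is not None
        assert len(exc.value.residual_history) == 3
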