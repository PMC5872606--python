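"""Hemodynamic metrics on synthetic (analytically known) flow fields."""

import numpy as np
import pytest

from stenoflow.errors import OutOfDomainError, StaleFieldError
from stenoflow.metrics import (
    poiseuille_sensitivity_check,
    pressure_drop,
    summarize,
    vortex_length,
    wall_pressure_profile,
    wall_shear_stress,
)

from conftest import Q_REF, R_REF, make_poiseuille_field

MU = 0.00345
UM = Q_REF / (np.pi * R_REF**2)


class TestWallShearStress:
    def test_poiseuille_wall_stress(self, poiseuille_field):
        xw, tau = wall_shear_stress(poiseuille_field)
        expected = 4.0 * MU * UM / R_REF
        assert np.allclose(tau, expected, rtol=5e-3)

    def test_zero_velocity_field_gives_zero(self, grid_straight_small):
        f = make_poiseuille_field(grid_straight_small)
        f.u[:] = 0.0
        f.v[:] = 0.0
        _, tau = wall_shear_stress(f)
        assert np.all(tau == 0.0)

    def test_unconverged_field_rejected(self, grid_straight_small):
        f = make_poiseuille_field(grid_straight_small, converged=False)
        with pytest.raises(StaleFieldError):
            wall_shear_stress(f)


class TestWallPressure:
    def test_profile_linear_and_gauged(self, poiseuille_field):
        xs, ps = wall_pressure_profile(poiseuille_field)
        assert xs[0] == pytest.approx(-3 * R_REF)
        assert xs[-1] == pytest.approx(9 * R_REF)
        assert ps[-1] == 0.0
        slope = np.polyfit(xs, ps, 1)[0]
        assert slope == pytest.approx(-8.0 * MU * UM / R_REF**2, rel=1e-2)
        # deviation from the best-fit line bounded by 1% of the total drop
        fit = np.polyval(np.polyfit(xs, ps, 1), xs)
        assert np.abs(ps - fit).max() <= 0.01 * (ps[0] - ps[-1])

    def test_pressure_drop_poiseuille(self, poiseuille_field):
        dp = pressure_drop(poiseuille_field)
        assert dp == pytest.approx(8.0 * MU * UM / R_REF**2 * 12.0 * R_REF, rel=1e-2)
        assert dp == pytest.approx(6.53, abs=0.1)

    def test_zero_flow_zero_drop(self, grid_straight_small):
        f = make_poiseuille_field(grid_straight_small)
        f.p[:] = 0.0
        f.grad_p[0][:] = 0.0
        assert pressure_drop(f) == pytest.approx(0.0, abs=1e-15)

    def test_window_outside_grid_rejected(self, poiseuille_field):
        R = R_REF
        with pytest.raises(OutOfDomainError):
            wall_pressure_profile(poiseuille_field, (-3 * R, 100 * R))


class TestVortexLength:
    def test_unidirectional_shear_has_no_vortex(self, poiseuille_field):
        L, sep, reat, nz = vortex_length(poiseuille_field)
        assert L == 0.0 and sep is None and reat is None and nz == 0

    def test_synthetic_recirculation_bubble(self, grid_straight_small):
        # impose a wall-row velocity changing sign at x1 and x2 > 0
        f = make_poiseuille_field(grid_straight_small)
        x1, x2 = 2.0 * R_REF, 7.0 * R_REF
        xw = f.grid.xc[:, -1]
        f.u[:, -1] = 1e-3 * (xw - x1) * (xw - x2) / R_REF**2
        L, sep, reat, nz = vortex_length(f)
        assert nz == 1
        assert sep == pytest.approx(x1, abs=0.05 * R_REF)
        assert reat == pytest.approx(x2, abs=0.05 * R_REF)
        assert L == pytest.approx((x2 - x1) / R_REF, rel=2e-2)

    def test_two_bubbles_returns_longest_and_flags_count(self, grid_straight_small):
        f = make_poiseuille_field(grid_straight_small)
        xw = f.grid.xc[:, -1]
        x1, x2, x3, x4 = 1.0 * R_REF, 2.0 * R_REF, 4.0 * R_REF, 9.0 * R_REF
        poly = (xw - x1) * (xw - x2) * (xw - x3) * (xw - x4)
        f.u[:, -1] = 1e-3 * poly / R_REF**4
        L, sep, reat, nz = vortex_length(f)
        assert nz == 2
        assert L == pytest.approx((x4 - x3) / R_REF, rel=2e-2)


class TestSensitivity:
    @pytest.mark.parametrize("delta, expected", [(-0.01, 0.04), (0.0, 0.0), (0.02, -0.08)])
    def test_linearized_prediction(self, delta, expected):
        assert poiseuille_sensitivity_check(delta) == pytest.approx(expected, abs=1e-15)


class TestSummary:
    def test_summarize_poiseuille(self, poiseuille_field):
        s = summarize(poiseuille_field)
        assert s.eta == 0.0
        assert s.rheology == "newtonian"
        assert s.vortex_length_over_R == 0.0
        assert s.delta_p == pytest.approx(6.53, abs=0.1)
        assert s.wss_peak == pytest.approx(4.0 * MU * UM / R_REF, rel=5e-3)
        rec = s.to_record()
        assert rec["separation_x_mm"] is None
        assert rec["delta_p_Pa"] == pytest.approx(s.delta_p)
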