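"""Closed-form and semi-analytic references for fully developed pipe flow.

Two solutions are provided:

* :func:`poiseuille` — the classical Newtonian parabola
  ``u(r) = 2 Um (1 - r^2/R^2)`` with ``dp/dx = -8 mu Um / R^2`` and
  ``tau_w = 4 mu Um / R``.
* :func:`developed_gn_pipe_flow` — steady, fully developed flow of any
  generalized-Newtonian fluid.  In such a flow the shear stress is exactly
  ``tau(r) = |dp/dx| r / 2``; since ``mu(gdot)*gdot`` is strictly
  increasing for the Carreau law, the local shear rate follows from a
  bracketed inversion, the velocity from ``u(r) = int_r^R gdot(s) ds``,
  and the pressure gradient from an outer root-find that closes the flow
  rate ``Q = int_0^R 2 pi r u dr`` to 1e-8 relative.

These serve as independent validation oracles for the finite-volume
solver (straight-tube cases) and supply its fully developed inlet profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .errors import OracleError
from .rheology import RheologyModel, viscosity

__all__ = ["DevelopedPipeSolution", "poiseuille", "developed_gn_pipe_flow"]

_NPROFILE = 4001  # radial samples for the tabulated profile


@dataclass(frozen=True)
class DevelopedPipeSolution:
    """Fully developed axisymmetric pipe-flow solution.

    ``u_of_r``/``gamma_of_r``/``mu_of_r`` evaluate the profile at arbitrary
    radii in ``[0, R]``; ``flux_cumulative(r)`` returns the per-radian
    volumetric flux ``int_0^r u(s) s ds`` used for exact-as-possible
    face-integrated inflow conditions.
    """

    R: float
    Q: float
    dpdx: float          # axial pressure gradient, negative for Q > 0 [Pa/m]
    tau_w: float         # wall shear stress magnitude [Pa]
    Um: float            # mean velocity Q/(pi R^2) [m/s]
    Q_check: float       # flow rate recovered by quadrature [m^3/s]
    u_of_r: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    gamma_of_r: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    mu_of_r: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    flux_cumulative: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    @property
    def centerline_velocity(self) -> float:
        return float(self.u_of_r(0.0))


def _validate_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if not (value > 0.0):
            raise ValueError(f"{name} must be positive, got {value!r}")


def poiseuille(R: float, Q: float, mu: float) -> DevelopedPipeSolution:
    """Newtonian fully developed pipe flow in closed form."""
    _validate_positive(R=R, Q=Q, mu=mu)
    Um = Q / (np.pi * R**2)
    dpdx = -8.0 * mu * Um / R**2
    tau_w = 4.0 * mu * Um / R

    def u_of_r(r):
        r = np.asarray(r, dtype=float)
        return 2.0 * Um * (1.0 - (r / R) ** 2)

    def gamma_of_r(r):
        r = np.asarray(r, dtype=float)
        return 4.0 * Um * r / R**2

    def mu_of_r(r):
        return np.full_like(np.asarray(r, dtype=float), mu)

    def flux_cumulative(r):
        r = np.asarray(r, dtype=float)
        return Um * (r**2 - 0.5 * r**4 / R**2)

    return DevelopedPipeSolution(
        R=R, Q=Q, dpdx=float(dpdx), tau_w=float(tau_w), Um=float(Um),
        Q_check=float(Q), u_of_r=u_of_r, gamma_of_r=gamma_of_r,
        mu_of_r=mu_of_r, flux_cumulative=flux_cumulative,
    )


def _invert_shear_rate(model: RheologyModel, tau: np.ndarray) -> np.ndarray:
    """Solve ``mu(g)*g = tau`` for ``g >= 0`` elementwise by bisection.

    For a shear-thinning Carreau fluid ``mu(g)*g`` is strictly increasing,
    and ``tau/mu_0 <= g <= tau/mu_inf`` brackets the root.
    """
    tau = np.asarray(tau, dtype=float)
    if model.kind == "newtonian":
        return tau / model.mu
    lo = tau / model.mu_0
    hi = tau / model.mu_inf
    # 80 bisection steps: interval shrinks by 2^80, far below any tolerance.
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        f = viscosity(model, mid) * mid - tau
        hi = np.where(f >= 0.0, mid, hi)
        lo = np.where(f >= 0.0, lo, mid)
    return 0.5 * (lo + hi)


def developed_gn_pipe_flow(R: float, Q: float, model: RheologyModel) -> DevelopedPipeSolution:
    """Semi-analytic fully developed generalized-Newtonian pipe flow."""
    _validate_positive(R=R, Q=Q)
    if model.kind == "newtonian":
        return poiseuille(R, Q, model.mu)

    Um = Q / (np.pi * R**2)
    # Radial grid (uniform, fine) for profile tabulation and quadrature.
    s = np.linspace(0.0, R, _NPROFILE)

    def flow_rate(dpdx_mag: float) -> float:
        gdot = _invert_shear_rate(model, 0.5 * dpdx_mag * s)
        # Q = pi * int_0^R gdot(s) s^2 ds  (integration by parts of 2*pi*r*u)
        return np.pi * np.trapezoid(gdot * s**2, s)

    # flow_rate is strictly increasing in |dp/dx|.  The gradient that would
    # drive Q through a constant-viscosity mu_inf fluid underestimates the
    # required one (the real fluid is more viscous everywhere); the mu_0
    # gradient overestimates it.
    lo = 8.0 * model.mu_inf * Um / R**2
    hi = 8.0 * model.mu_0 * Um / R**2
    flo, fhi = flow_rate(lo) - Q, flow_rate(hi) - Q
    tries = 0
    while flo > 0.0:
        lo *= 0.5
        flo = flow_rate(lo) - Q
        tries += 1
        if tries > 60:
            raise OracleError(f"could not bracket dp/dx from below (lo={lo})")
    while fhi < 0.0:
        hi *= 2.0
        fhi = flow_rate(hi) - Q
        tries += 1
        if tries > 120:
            raise OracleError(f"could not bracket dp/dx from above (hi={hi})")
    if flo * fhi > 0.0:
        raise OracleError(
            f"dp/dx bracket does not straddle the target flow rate: "
            f"[{lo}, {hi}] -> [{flo + Q}, {fhi + Q}] vs Q={Q}"
        )
    dpdx_mag = brentq(lambda g: flow_rate(g) - Q, lo, hi, xtol=1e-30, rtol=1e-14)

    gdot_s = _invert_shear_rate(model, 0.5 * dpdx_mag * s)
    # u(r) = int_r^R gdot ds, tabulated by cumulative trapezoid from the wall.
    du = np.concatenate(([0.0], np.cumsum(0.5 * (gdot_s[1:] + gdot_s[:-1]) * np.diff(s))))
    u_s = du[-1] - du
    q_cum = np.concatenate(
        ([0.0], np.cumsum(0.5 * (u_s[1:] * s[1:] + u_s[:-1] * s[:-1]) * np.diff(s)))
    )
    Q_check = float(flow_rate(dpdx_mag))
    mu_s = viscosity(model, gdot_s)

    def u_of_r(r):
        return np.interp(np.abs(np.asarray(r, dtype=float)), s, u_s)

    def gamma_of_r(r):
        return np.interp(np.abs(np.asarray(r, dtype=float)), s, gdot_s)

    def mu_of_r(r):
        return np.interp(np.abs(np.asarray(r, dtype=float)), s, mu_s)

    def flux_cumulative(r):
        return np.interp(np.abs(np.asarray(r, dtype=float)), s, q_cum)

    return DevelopedPipeSolution(
        R=R, Q=Q, dpdx=-float(dpdx_mag), tau_w=float(0.5 * dpdx_mag * R),
        Um=float(Um), Q_check=Q_check, u_of_r=u_of_r, gamma_of_r=gamma_of_r,
        mu_of_r=mu_of_r, flux_cumulative=flux_cumulative,
    )
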