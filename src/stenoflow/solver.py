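"""Steady axisymmetric SIMPLE finite-volume solver with variable viscosity.

Discretization summary
----------------------
* Colocated cell-centered variables ``(u, v, p)`` on the boundary-fitted
  structured grid, with Rhie–Chow momentum-weighted interpolation for the
  face mass fluxes (suppresses pressure checkerboarding).
* Convection: implicit first-order upwind plus an explicit deferred
  correction to second-order (linear) upwind.
* Diffusion: implicit over-relaxed orthogonal part, explicit cross
  (non-orthogonal) correction; the transposed velocity-gradient part of
  the stress ``mu*(grad U)^T`` is explicit (it matters when ``mu`` varies).
* Axisymmetry: all face areas/volumes carry the ``r`` weight (per radian);
  the radial momentum equation carries the hoop sources
  ``+ int p dA`` (from ``-dp/dr``) and ``- 2 mu v / r`` per unit volume.
* Pressure–velocity coupling: SIMPLE with under-relaxation of momentum
  and pressure; the pressure-correction equation takes a homogeneous
  Dirichlet value on the outlet plane, which pins the gauge.

Boundary conditions: prescribed inflow profile (fully developed for the
active rheology, or uniform), no-slip wall, symmetry axis (automatic:
revolved face areas vanish at ``r = 0``), zero-gradient outflow with the
outflow fluxes rescaled every iteration to conserve the flow rate.

All equations are per unit azimuthal radian; the physical flow rate ``Q``
enters as ``Q / (2 pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import (
    ConfigurationError,
    ConvergenceError,
    NumericalBreakdownError,
)
from .grid import AxisymmetricGrid
from .oracles import developed_gn_pipe_flow
from .rheology import RheologyModel, shear_rate, viscosity

__all__ = [
    "BoundaryConditions",
    "NumericsConfig",
    "FlowField",
    "SimpleSolver",
    "solve_steady",
    "momentum_assembly",
    "pressure_correction",
]


@dataclass(frozen=True)
class BoundaryConditions:
    """Inflow/outflow specification.

    Q : volumetric flow rate [m^3/s].
    rho : fluid density [kg/m^3].
    inlet_profile : ``"fully_developed"`` (profile of the active rheology,
        computed semi-analytically) or ``"uniform"``.
    outlet : only ``"zero_gradient"`` is supported.
    p_reference : gauge convention; the solver pins the pressure level at
        the outlet plane (metrics re-gauge to p = 0 at x = 9R on the wall).
    """

    Q: float
    rho: float
    inlet_profile: str = "fully_developed"
    outlet: str = "zero_gradient"
    p_reference: tuple = ("outlet", 0.0)

    def __post_init__(self) -> None:
        if not self.Q > 0.0:
            raise ConfigurationError(f"flow rate must be positive, got {self.Q!r}")
        if not self.rho > 0.0:
            raise ConfigurationError(f"density must be positive, got {self.rho!r}")
        if self.inlet_profile not in ("fully_developed", "uniform"):
            raise ConfigurationError(f"unknown inlet profile {self.inlet_profile!r}")
        if self.outlet != "zero_gradient":
            raise ConfigurationError(f"unknown outlet condition {self.outlet!r}")

    def mean_velocity(self, R: float) -> float:
        return self.Q / (np.pi * R**2)


@dataclass(frozen=True)
class NumericsConfig:
    """SIMPLE iteration controls.

    Defaults: momentum under-relaxation 0.7, pressure 0.3, viscosity 0.7;
    normalized residual tolerances 1e-6; second-order upwind convection.
    """

    relax_u: float = 0.7
    relax_p: float = 0.3
    relax_mu: float = 0.7
    tol_mass: float = 1e-6
    tol_mom: float = 1e-6
    max_iter: int = 5000
    convection_scheme: str = "second_order_upwind"
    raise_on_fail: bool = True

    def __post_init__(self) -> None:
        for name in ("relax_u", "relax_p", "relax_mu"):
            val = getattr(self, name)
            if not (0.0 < val <= 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1], got {val!r}")
        if not (self.tol_mass > 0.0 and self.tol_mom > 0.0):
            raise ConfigurationError("tolerances must be positive")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        if self.convection_scheme not in ("second_order_upwind", "first_order_upwind"):
            raise ConfigurationError(
                f"unknown convection scheme {self.convection_scheme!r}"
            )


@dataclass
class FlowField:
    """Converged (or partially converged) discrete solution.

    ``u, v, p, mu_eff`` are cell-centered ``(nx, nr)`` arrays; ``Fx, Fr``
    are the conservative per-radian face mass fluxes; ``residual_history``
    has columns (iteration, mass, u-momentum, v-momentum), all normalized.
    """

    grid: AxisymmetricGrid
    rheology: RheologyModel
    bc: BoundaryConditions
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    mu_eff: np.ndarray
    Fx: np.ndarray
    Fr: np.ndarray
    grad_p: tuple
    residual_history: np.ndarray
    converged: bool
    n_iter: int

    def flux_profile(self) -> np.ndarray:
        """Volume flux [m^3/s] through every axial face plane."""
        return 2.0 * np.pi * self.Fx.sum(axis=1) / self.bc.rho

    def to_dataframe(self):
        """Cell-centered fields as a tidy DataFrame (x, r in meters)."""
        import pandas as pd

        g = self.grid
        return pd.DataFrame(
            {
                "x": g.xc.ravel(),
                "r": g.rc.ravel(),
                "u": self.u.ravel(),
                "v": self.v.ravel(),
                "p": self.p.ravel(),
                "mu_eff": self.mu_eff.ravel(),
            }
        )


def _inlet_face_data(grid: AxisymmetricGrid, rheology: RheologyModel,
                     bc: BoundaryConditions):
    """Face-integrated inflow fluxes (per radian) and face-center velocities."""
    R = grid.geom.R
    rv = grid.vertex_r[0, :]                       # inlet vertex radii
    if abs(grid.geom.wall_radius(grid.x_faces[0]) - R) > 1e-12 * R:
        raise ConfigurationError("inlet plane must lie in the straight tube section")
    if bc.inlet_profile == "uniform":
        Um = bc.mean_velocity(R)
        q = 0.5 * Um * (rv[1:] ** 2 - rv[:-1] ** 2)
        u_face = np.full(grid.nr, Um)
    else:
        sol = developed_gn_pipe_flow(R, bc.Q, rheology)
        q = sol.flux_cumulative(rv[1:]) - sol.flux_cumulative(rv[:-1])
        u_face = sol.u_of_r(grid.iface_rc[0, :])
    # normalize the discrete flux sum to exactly Q/(2 pi)
    q *= (bc.Q / (2.0 * np.pi)) / q.sum()
    return q, u_face


class SimpleSolver:
    """Stateful SIMPLE iteration on one grid/rheology/BC combination.

    Most users should call :func:`solve_steady`; the class is exposed so
    that individual stages (momentum assembly, pressure correction) can be
    exercised and tested in isolation.
    """

    def __init__(
        self,
        grid: AxisymmetricGrid,
        rheology: RheologyModel,
        bc: BoundaryConditions,
        cfg: Optional[NumericsConfig] = None,
    ):
        self.grid = grid
        self.rheology = rheology
        self.bc = bc
        self.cfg = cfg if cfg is not None else NumericsConfig()
        self._precompute_geometry()
        self._init_fields()

    # ------------------------------------------------------------------
    # geometry precomputation
    # ------------------------------------------------------------------
    def _precompute_geometry(self) -> None:
        g = self.grid
        nx, nr = g.nx, g.nr
        self.nx, self.nr = nx, nr
        xc, rc = g.xc, g.rc
        xf = g.x_faces

        # --- interior i-faces (between columns), faces 1..nx-1 ---
        dxi = xc[1:, :] - xc[:-1, :]
        dri = rc[1:, :] - rc[:-1, :]
        Si = g.iface_S[1:-1, :]
        self.Si = Si
        self.Di_geom = Si / dxi                     # implicit diffusion metric
        self.Ti_r = -Si * dri / dxi                 # cross-diffusion vector (x-comp 0)
        self.dxi, self.dri = dxi, dri
        self.wNi = (xf[1:-1][:, None] - xc[:-1, :]) / dxi
        fcx_i = np.broadcast_to(xf[1:-1][:, None], Si.shape)
        fcr_i = g.iface_rc[1:-1, :]
        # offsets from owner/neighbor centroids to face center (for SOU)
        self.d_up_P_i = (fcx_i - xc[:-1, :], fcr_i - rc[:-1, :])
        self.d_up_N_i = (fcx_i - xc[1:, :], fcr_i - rc[1:, :])
        # skewness offset from weighted midpoint to face center
        wmx = self.wNi * xc[1:, :] + (1 - self.wNi) * xc[:-1, :]
        wmr = self.wNi * rc[1:, :] + (1 - self.wNi) * rc[:-1, :]
        self.skew_i = (fcx_i - wmx, fcr_i - wmr)

        # --- interior j-faces (between rows), faces 1..nr-1 ---
        Sjx = g.jface_Sx[:, 1:-1]
        Sjr = g.jface_Sr[:, 1:-1]
        Sj2 = Sjx**2 + Sjr**2
        dxj = xc[:, 1:] - xc[:, :-1]
        drj = rc[:, 1:] - rc[:, :-1]
        Sd = Sjx * dxj + Sjr * drj
        self.Sjx, self.Sjr = Sjx, Sjr
        self.Dj_geom = Sj2 / Sd
        self.Tjx = Sjx - (Sj2 / Sd) * dxj
        self.Tjr = Sjr - (Sj2 / Sd) * drj
        self.dxj, self.drj = dxj, drj
        fcx_j = g.jface_xc[:, 1:-1]
        fcr_j = g.jface_rc[:, 1:-1]
        self.wNj = ((fcx_j - xc[:, :-1]) * Sjx + (fcr_j - rc[:, :-1]) * Sjr) / Sd
        self.d_up_P_j = (fcx_j - xc[:, :-1], fcr_j - rc[:, :-1])
        self.d_up_N_j = (fcx_j - xc[:, 1:], fcr_j - rc[:, 1:])
        wmx = self.wNj * xc[:, 1:] + (1 - self.wNj) * xc[:, :-1]
        wmr = self.wNj * rc[:, 1:] + (1 - self.wNj) * rc[:, :-1]
        self.skew_j = (fcx_j - wmx, fcr_j - wmr)

        # --- boundary faces ---
        self.S_in = g.iface_S[0, :]
        self.dx_in = xc[0, :] - xf[0]
        self.S_out = g.iface_S[-1, :]
        self.dx_out = xf[-1] - xc[-1, :]
        # wall (top j-face)
        Swx, Swr = g.jface_Sx[:, -1], g.jface_Sr[:, -1]
        Sw = np.hypot(Swx, Swr)
        dbx = g.jface_xc[:, -1] - xc[:, -1]
        dbr = g.jface_rc[:, -1] - rc[:, -1]
        Sdw = Swx * dbx + Swr * dbr
        self.Swx, self.Swr, self.Sw = Swx, Swr, Sw
        self.Dw_geom = Sw**2 / Sdw
        self.Twx = Swx - (Sw**2 / Sdw) * dbx
        self.Twr = Swr - (Sw**2 / Sdw) * dbr
        self.wall_dn = Sdw / Sw                     # centroid-to-wall normal distance
        self.wall_tx = Swr / Sw                     # wall tangent, +x oriented
        self.wall_tr = -Swx / Sw
        # axis faces: revolved area is zero; only planar vectors matter (GG)
        # boundary face offsets for pressure extrapolation
        self.db_in = (xf[0] - xc[0, :], g.iface_rc[0, :] - rc[0, :])
        self.db_out = (xf[-1] - xc[-1, :], g.iface_rc[-1, :] - rc[-1, :])
        self.db_wall = (dbx, dbr)
        self.db_axis = (g.jface_xc[:, 0] - xc[:, 0], g.jface_rc[:, 0] - rc[:, 0])

        # planar face vectors for Green-Gauss gradients
        self.Pi = g.iface_plan                       # (nx+1, nr), x-component
        self.Pjx, self.Pjr = g.jface_Px, g.jface_Pr  # (nx, nr+1)
        self.A_plan = g.area_plan
        self.vol = g.vol

        # sparse assembly helpers
        self.ncell = nx * nr

    # ------------------------------------------------------------------
    # field initialization
    # ------------------------------------------------------------------
    def _init_fields(self) -> None:
        g = self.grid
        bc = self.bc
        self.q_in, self.u_in = _inlet_face_data(g, self.rheology, bc)
        self.Q_rad = bc.Q / (2.0 * np.pi)
        self.Um = bc.mean_velocity(g.geom.R)
        self._mom_norm = bc.rho * bc.Q / (2.0 * np.pi) * self.Um
        self._mass_norm = bc.rho * self.Q_rad

        sol = developed_gn_pipe_flow(g.geom.R, bc.Q, self.rheology)
        rw_col = 0.5 * (g.vertex_r[:-1, -1] + g.vertex_r[1:, -1])  # wall radius per column
        scale = (g.geom.R / rw_col) ** 2
        zeta = g.rc / rw_col[:, None]              # radial fraction of local radius
        self.u = sol.u_of_r(zeta * g.geom.R) * scale[:, None]
        self.v = np.zeros_like(self.u)
        self.p = np.zeros_like(self.u)
        self.mu = np.full_like(self.u, viscosity(self.rheology, 0.0)
                               if self.rheology.kind == "carreau" else self.rheology.mu)
        if self.rheology.kind == "carreau":
            self.mu = sol.mu_of_r(np.clip(zeta, 0.0, 1.0) * g.geom.R)
        self.gpx = np.zeros_like(self.u)
        self.gpr = np.zeros_like(self.u)
        self._set_initial_fluxes()
        self.history: list[tuple] = []
        self.n_iter = 0
        self.converged = False

    def set_field(self, u=None, v=None, p=None) -> None:
        """Overwrite the current iterate (used for warm starts and tests)."""
        if u is not None:
            self.u = np.array(u, dtype=float)
        if v is not None:
            self.v = np.array(v, dtype=float)
        if p is not None:
            self.p = np.array(p, dtype=float)
        self._update_viscosity(relax=1.0)
        self._set_initial_fluxes()

    def _set_initial_fluxes(self) -> None:
        nx, nr = self.nx, self.nr
        Fx = np.zeros((nx + 1, nr))
        Fr = np.zeros((nx, nr + 1))
        rho = self.bc.rho
        uf = self.wNi * self.u[1:, :] + (1 - self.wNi) * self.u[:-1, :]
        Fx[1:-1, :] = rho * uf * self.Si
        Fx[0, :] = rho * self.q_in
        Fx[-1, :] = rho * self.u[-1, :] * self.S_out
        tot = Fx[-1, :].sum()
        if tot > 0.0:
            Fx[-1, :] *= rho * self.Q_rad / tot
        ufj = self.wNj * self.u[:, 1:] + (1 - self.wNj) * self.u[:, :-1]
        vfj = self.wNj * self.v[:, 1:] + (1 - self.wNj) * self.v[:, :-1]
        Fr[:, 1:-1] = rho * (ufj * self.Sjx + vfj * self.Sjr)
        self.Fx, self.Fr = Fx, Fr
        defect = Fx[1:, :] - Fx[:-1, :] + Fr[:, 1:] - Fr[:, :-1]
        self._last_mass_res = np.abs(defect).sum() / self._mass_norm

    # ------------------------------------------------------------------
    # gradients
    # ------------------------------------------------------------------
    def _face_values(self, phi, bval_in, bval_out, bval_axis, bval_wall):
        """Distance-weighted face interpolation with prescribed boundary values."""
        pif = np.empty((self.nx + 1, self.nr))
        pif[1:-1, :] = self.wNi * phi[1:, :] + (1 - self.wNi) * phi[:-1, :]
        pif[0, :] = bval_in
        pif[-1, :] = bval_out
        pjf = np.empty((self.nx, self.nr + 1))
        pjf[:, 1:-1] = self.wNj * phi[:, 1:] + (1 - self.wNj) * phi[:, :-1]
        pjf[:, 0] = bval_axis
        pjf[:, -1] = bval_wall
        return pif, pjf

    def _grad_gg(self, pif, pjf):
        """Planar Green-Gauss gradient from prescribed face values."""
        gx = (
            pif[1:, :] * self.Pi[1:, :] - pif[:-1, :] * self.Pi[:-1, :]
            + pjf[:, 1:] * self.Pjx[:, 1:] - pjf[:, :-1] * self.Pjx[:, :-1]
        ) / self.A_plan
        gr = (
            pjf[:, 1:] * self.Pjr[:, 1:] - pjf[:, :-1] * self.Pjr[:, :-1]
        ) / self.A_plan
        return gx, gr

    def velocity_gradients(self):
        """Green-Gauss gradients of (u, v) honoring the boundary values."""
        uif, ujf = self._face_values(
            self.u, self.u_in, self.u[-1, :], self.u[:, 0], 0.0
        )
        vif, vjf = self._face_values(
            self.v, 0.0, self.v[-1, :], 0.0, 0.0
        )
        gux, gur = self._grad_gg(uif, ujf)
        gvx, gvr = self._grad_gg(vif, vjf)
        return gux, gur, gvx, gvr

    def _pressure_faces(self, p, gpx, gpr):
        """Face pressures: skew-corrected interior, gradient-extrapolated boundary."""
        pif = np.empty((self.nx + 1, self.nr))
        gxf = self.wNi * gpx[1:, :] + (1 - self.wNi) * gpx[:-1, :]
        grf = self.wNi * gpr[1:, :] + (1 - self.wNi) * gpr[:-1, :]
        pif[1:-1, :] = (
            self.wNi * p[1:, :] + (1 - self.wNi) * p[:-1, :]
            + gxf * self.skew_i[0] + grf * self.skew_i[1]
        )
        pif[0, :] = p[0, :] + gpx[0, :] * self.db_in[0] + gpr[0, :] * self.db_in[1]
        pif[-1, :] = p[-1, :] + gpx[-1, :] * self.db_out[0] + gpr[-1, :] * self.db_out[1]
        pjf = np.empty((self.nx, self.nr + 1))
        gxf = self.wNj * gpx[:, 1:] + (1 - self.wNj) * gpx[:, :-1]
        grf = self.wNj * gpr[:, 1:] + (1 - self.wNj) * gpr[:, :-1]
        pjf[:, 1:-1] = (
            self.wNj * p[:, 1:] + (1 - self.wNj) * p[:, :-1]
            + gxf * self.skew_j[0] + grf * self.skew_j[1]
        )
        pjf[:, 0] = p[:, 0] + gpx[:, 0] * self.db_axis[0] + gpr[:, 0] * self.db_axis[1]
        pjf[:, -1] = p[:, -1] + gpx[:, -1] * self.db_wall[0] + gpr[:, -1] * self.db_wall[1]
        return pif, pjf

    def pressure_gradient(self, p):
        """r-weighted (axisymmetric) cell pressure gradient, two-pass boundary
        extrapolation seeded with the stored gradient of the previous call."""
        g = self.grid
        gpx, gpr = self.gpx, self.gpr
        for _ in range(2):
            pif, pjf = self._pressure_faces(p, gpx, gpr)
            gpx = (
                pif[1:, :] * g.iface_S[1:, :] - pif[:-1, :] * g.iface_S[:-1, :]
                + pjf[:, 1:] * g.jface_Sx[:, 1:] - pjf[:, :-1] * g.jface_Sx[:, :-1]
            ) / self.vol
            gpr = (
                pjf[:, 1:] * g.jface_Sr[:, 1:] - pjf[:, :-1] * g.jface_Sr[:, :-1]
                - p * self.A_plan
            ) / self.vol
        self.gpx, self.gpr = gpx, gpr
        self._p_faces = (pif, pjf)
        return gpx, gpr

    # ------------------------------------------------------------------
    # viscosity
    # ------------------------------------------------------------------
    def _update_viscosity(self, relax=None) -> None:
        if self.rheology.kind == "newtonian":
            self.mu = np.full((self.nx, self.nr), self.rheology.mu)
            self._gradU = self.velocity_gradients()
            return
        gux, gur, gvx, gvr = self.velocity_gradients()
        self._gradU = (gux, gur, gvx, gvr)
        gdot = shear_rate(gux, gur, gvx, gvr, self.v, self.grid.rc)
        mu_new = viscosity(self.rheology, gdot)
        alpha = self.cfg.relax_mu if relax is None else relax
        self.mu = alpha * mu_new + (1.0 - alpha) * self.mu

    def _wall_viscosity(self) -> np.ndarray:
        if self.rheology.kind == "newtonian":
            return np.full(self.nx, self.rheology.mu)
        ut = self.u[:, -1] * self.wall_tx + self.v[:, -1] * self.wall_tr
        gdot_w = np.abs(ut) / self.wall_dn
        return viscosity(self.rheology, gdot_w)

    # ------------------------------------------------------------------
    # momentum assembly
    # ------------------------------------------------------------------
    def momentum_assembly(self):
        """Assemble the linearized (unrelaxed) momentum systems.

        Returns ``(A_u, b_u, A_v, b_v, diag_u, diag_v)`` with matrices in
        CSC format over the ``nx*nr`` cell unknowns (row-major, radial
        index fastest).
        """
        nx, nr = self.nx, self.nr
        mu, u, v = self.mu, self.u, self.v
        Fx, Fr = self.Fx, self.Fr
        gux, gur, gvx, gvr = self._gradU
        gpx, gpr = self.pressure_gradient(self.p)

        mu_if = self.wNi * mu[1:, :] + (1 - self.wNi) * mu[:-1, :]
        mu_jf = self.wNj * mu[:, 1:] + (1 - self.wNj) * mu[:, :-1]
        mu_w = self._wall_viscosity()
        mu_in = mu[0, :]

        Di = mu_if * self.Di_geom                   # (nx-1, nr)
        Dj = mu_jf * self.Dj_geom                   # (nx, nr-1)
        Dw = mu_w * self.Dw_geom                    # (nx,)
        Din = mu_in * self.S_in / self.dx_in        # (nr,)

        Fxi = Fx[1:-1, :]
        Frj = Fr[:, 1:-1]

        aE = Di + np.maximum(-Fxi, 0.0)             # cell (i,j) -> (i+1,j)
        aW = Di + np.maximum(Fxi, 0.0)              # cell (i+1,j) -> (i,j)
        aN = Dj + np.maximum(-Frj, 0.0)
        aS = Dj + np.maximum(Frj, 0.0)

        diag = np.zeros((nx, nr))
        diag[:-1, :] += aE
        diag[1:, :] += aW
        diag[:, :-1] += aN
        diag[:, 1:] += aS
        diag[0, :] += Din + np.maximum(Fx[0, :], 0.0)
        diag[:, -1] += Dw                           # wall, no-slip (F = 0)
        # outlet: zero-gradient convection cancels against the continuity fix

        # ---- explicit sources shared pieces ----
        b_u = np.zeros((nx, nr))
        b_v = np.zeros((nx, nr))

        # pressure force (r-weighted Green-Gauss)
        b_u -= gpx * self.vol
        b_v -= gpr * self.vol

        # inlet Dirichlet contributions
        b_u[0, :] += (Din + np.maximum(Fx[0, :], 0.0)) * self.u_in
        # v_in = 0, wall values are 0: no source from those Dirichlet faces

        if self.cfg.convection_scheme == "second_order_upwind":
            self._add_sou_correction(b_u, u, gux, gur, Fxi, Frj, self.u_in)
            self._add_sou_correction(b_v, v, gvx, gvr, Fxi, Frj, 0.0)

        # cross-diffusion (non-orthogonal correction), interior faces
        gur_f = self.wNi * gur[1:, :] + (1 - self.wNi) * gur[:-1, :]
        cd_i = mu_if * gur_f * self.Ti_r            # i-face T has only r-component
        b_u[:-1, :] += cd_i
        b_u[1:, :] -= cd_i
        gvr_f = self.wNi * gvr[1:, :] + (1 - self.wNi) * gvr[:-1, :]
        cd_i = mu_if * gvr_f * self.Ti_r
        b_v[:-1, :] += cd_i
        b_v[1:, :] -= cd_i
        gux_f = self.wNj * gux[:, 1:] + (1 - self.wNj) * gux[:, :-1]
        gur_fj = self.wNj * gur[:, 1:] + (1 - self.wNj) * gur[:, :-1]
        cd_j = mu_jf * (gux_f * self.Tjx + gur_fj * self.Tjr)
        b_u[:, :-1] += cd_j
        b_u[:, 1:] -= cd_j
        gvx_f = self.wNj * gvx[:, 1:] + (1 - self.wNj) * gvx[:, :-1]
        gvr_fj = self.wNj * gvr[:, 1:] + (1 - self.wNj) * gvr[:, :-1]
        cd_j = mu_jf * (gvx_f * self.Tjx + gvr_fj * self.Tjr)
        b_v[:, :-1] += cd_j
        b_v[:, 1:] -= cd_j
        # wall face cross-diffusion (owner gradient)
        b_u[:, -1] += mu_w * (gux[:, -1] * self.Twx + gur[:, -1] * self.Twr)
        b_v[:, -1] += mu_w * (gvx[:, -1] * self.Twx + gvr[:, -1] * self.Twr)

        # transposed stress mu*(grad U)^T . S (explicit, face-interpolated)
        gux_fi = self.wNi * gux[1:, :] + (1 - self.wNi) * gux[:-1, :]
        tr_i = mu_if * gux_fi * self.Si             # x-comp of S only
        b_u[:-1, :] += tr_i
        b_u[1:, :] -= tr_i
        gvx_fi = self.wNi * gvx[1:, :] + (1 - self.wNi) * gvx[:-1, :]
        gur_fi = self.wNi * gur[1:, :] + (1 - self.wNi) * gur[:-1, :]
        tr_iv = mu_if * gur_fi * self.Si
        b_v[:-1, :] += tr_iv
        b_v[1:, :] -= tr_iv
        gvx_fj = self.wNj * gvx[:, 1:] + (1 - self.wNj) * gvx[:, :-1]
        tr_j = mu_jf * (gux_f * self.Sjx + gvx_fj * self.Sjr)
        b_u[:, :-1] += tr_j
        b_u[:, 1:] -= tr_j
        gvr_fj2 = self.wNj * gvr[:, 1:] + (1 - self.wNj) * gvr[:, :-1]
        tr_jv = mu_jf * (gur_fj * self.Sjx + gvr_fj2 * self.Sjr)
        b_v[:, :-1] += tr_jv
        b_v[:, 1:] -= tr_jv
        # boundary faces: inlet (owner gradient), wall (owner gradient)
        b_u[0, :] -= mu_in * gux[0, :] * self.S_in      # outward normal is -x
        b_v[0, :] -= mu_in * gur[0, :] * self.S_in
        b_u[-1, :] += mu[-1, :] * gux[-1, :] * self.S_out
        b_v[-1, :] += mu[-1, :] * gur[-1, :] * self.S_out
        b_u[:, -1] += mu_w * (gux[:, -1] * self.Swx + gvx[:, -1] * self.Swr)
        b_v[:, -1] += mu_w * (gur[:, -1] * self.Swx + gvr[:, -1] * self.Swr)

        # radial momentum: hoop pressure is inside gpr; hoop viscous term
        # -2 mu v / r (implicit, positive diagonal)
        diag_v = diag + 2.0 * mu * self.A_plan / self.grid.rc
        diag_u = diag

        A_u = self._build_matrix(diag_u, aW, aE, aS, aN)
        A_v = self._build_matrix(diag_v, aW, aE, aS, aN)
        self._coef = (aW, aE, aS, aN)
        return A_u, b_u.ravel(), A_v, b_v.ravel(), diag_u, diag_v

    def _add_sou_correction(self, b, phi, gx, gr, Fxi, Frj, phi_in) -> None:
        """Deferred second-order (linear) upwind correction for one component."""
        up_is_P = Fxi >= 0.0
        phi_up = np.where(up_is_P, phi[:-1, :], phi[1:, :])
        corr = np.where(
            up_is_P,
            gx[:-1, :] * self.d_up_P_i[0] + gr[:-1, :] * self.d_up_P_i[1],
            gx[1:, :] * self.d_up_N_i[0] + gr[1:, :] * self.d_up_N_i[1],
        )
        dflux = Fxi * corr
        b[:-1, :] -= dflux
        b[1:, :] += dflux

        up_is_P = Frj >= 0.0
        corr = np.where(
            up_is_P,
            gx[:, :-1] * self.d_up_P_j[0] + gr[:, :-1] * self.d_up_P_j[1],
            gx[:, 1:] * self.d_up_N_j[0] + gr[:, 1:] * self.d_up_N_j[1],
        )
        dflux = Frj * corr
        b[:, :-1] -= dflux
        b[:, 1:] += dflux

    def _build_matrix(self, diag, aW, aE, aS, aN):
        nx, nr = self.nx, self.nr
        aN_full = np.zeros((nx, nr))
        aN_full[:, :-1] = aN
        aS_full = np.zeros((nx, nr))
        aS_full[:, 1:] = aS
        return sp.diags(
            [
                diag.ravel(),
                -aE.ravel(),                 # offset +nr
                -aW.ravel(),                 # offset -nr
                -aN_full.ravel()[:-1],       # offset +1
                -aS_full.ravel()[1:],        # offset -1
            ],
            [0, nr, -nr, 1, -1],
            format="csc",
        )

    # ------------------------------------------------------------------
    # Rhie-Chow fluxes and pressure correction
    # ------------------------------------------------------------------
    def _rhie_chow_fluxes(self, rAU) -> None:
        rho = self.bc.rho
        u, v, p = self.u, self.v, self.p
        gpx, gpr = self.gpx, self.gpr

        # i-faces
        uf = self.wNi * u[1:, :] + (1 - self.wNi) * u[:-1, :]
        rAUf = self.wNi * rAU[1:, :] + (1 - self.wNi) * rAU[:-1, :]
        gpx_f = self.wNi * gpx[1:, :] + (1 - self.wNi) * gpx[:-1, :]
        gpr_f = self.wNi * gpr[1:, :] + (1 - self.wNi) * gpr[:-1, :]
        dp_compact = p[1:, :] - p[:-1, :]
        gbar_d = gpx_f * self.dxi + gpr_f * self.dri
        Ei_over_d = self.Si * 1.0 / self.dxi        # E/|d| = S/dx for i-faces
        self.Fx[1:-1, :] = rho * (
            uf * self.Si - rAUf * (dp_compact - gbar_d) * Ei_over_d
        )
        self._cpi = rho * rAUf * Ei_over_d          # p' coupling coefficient

        # j-faces
        ufj = self.wNj * u[:, 1:] + (1 - self.wNj) * u[:, :-1]
        vfj = self.wNj * v[:, 1:] + (1 - self.wNj) * v[:, :-1]
        rAUfj = self.wNj * rAU[:, 1:] + (1 - self.wNj) * rAU[:, :-1]
        gpx_fj = self.wNj * gpx[:, 1:] + (1 - self.wNj) * gpx[:, :-1]
        gpr_fj = self.wNj * gpr[:, 1:] + (1 - self.wNj) * gpr[:, :-1]
        dp_compact = p[:, 1:] - p[:, :-1]
        gbar_d = gpx_fj * self.dxj + gpr_fj * self.drj
        self.Fr[:, 1:-1] = rho * (
            ufj * self.Sjx + vfj * self.Sjr
            - rAUfj * (dp_compact - gbar_d) * self.Dj_geom
        )
        self._cpj = rho * rAUfj * self.Dj_geom

        # boundaries: inlet fixed, wall/axis zero, outlet scaled zero-gradient
        self.Fx[0, :] = rho * self.q_in
        Fout = rho * np.maximum(u[-1, :], 0.0) * self.S_out
        tot = Fout.sum()
        if tot <= 0.0:
            # degenerate transient state: fall back to uniform outflow
            Fout = np.full(self.nr, 1.0) * self.S_out
            tot = Fout.sum()
        self.Fx[-1, :] = Fout * (rho * self.Q_rad / tot)
        self._cpo = rho * (rAU[-1, :]) * self.S_out / self.dx_out

    def pressure_correction(self):
        """Solve the SIMPLE pressure-correction equation and apply all
        corrections (pressure, cell velocities, face fluxes).

        Returns the pre-correction normalized mass residual.
        """
        nx, nr = self.nx, self.nr
        defect = (
            self.Fx[1:, :] - self.Fx[:-1, :] + self.Fr[:, 1:] - self.Fr[:, :-1]
        )
        mass_res = np.abs(defect).sum() / self._mass_norm

        self._last_mass_res = mass_res
        cpi, cpj, cpo = self._cpi, self._cpj, self._cpo
        diag = np.zeros((nx, nr))
        diag[:-1, :] += cpi
        diag[1:, :] += cpi
        diag[:, :-1] += cpj
        diag[:, 1:] += cpj
        diag[-1, :] += cpo
        A = self._build_matrix(diag, cpi, cpi, cpj, cpj)
        pc = splu(A).solve(-defect.ravel()).reshape(nx, nr)

        # flux corrections
        self.Fx[1:-1, :] -= cpi * (pc[1:, :] - pc[:-1, :])
        self.Fr[:, 1:-1] -= cpj * (pc[:, 1:] - pc[:, :-1])
        self.Fx[-1, :] += cpo * pc[-1, :]

        # pressure (relaxed) and velocity corrections
        self.p = self.p + self.cfg.relax_p * pc
        gcx, gcr = self._pc_gradient(pc)
        self.u = self.u - self._rAU * gcx
        self.v = self.v - self._rAU * gcr
        return mass_res

    def _pc_gradient(self, pc):
        """r-weighted gradient of the pressure correction (zero-gradient
        boundaries except homogeneous Dirichlet at the outlet)."""
        g = self.grid
        pif, pjf = self._face_values(pc, pc[0, :], 0.0, pc[:, 0], pc[:, -1])
        gx = (
            pif[1:, :] * g.iface_S[1:, :] - pif[:-1, :] * g.iface_S[:-1, :]
            + pjf[:, 1:] * g.jface_Sx[:, 1:] - pjf[:, :-1] * g.jface_Sx[:, :-1]
        ) / self.vol
        gr = (
            pjf[:, 1:] * g.jface_Sr[:, 1:] - pjf[:, :-1] * g.jface_Sr[:, :-1]
            - pc * self.A_plan
        ) / self.vol
        return gx, gr

    # ------------------------------------------------------------------
    # main loop
    # ------------------------------------------------------------------
    def iterate(self, max_iter=None, log=None):
        cfg = self.cfg
        max_iter = cfg.max_iter if max_iter is None else max_iter
        alpha = cfg.relax_u
        for _ in range(max_iter):
            self.n_iter += 1
            self._update_viscosity()
            A_u, b_u, A_v, b_v, diag_u, diag_v = self.momentum_assembly()

            u_flat, v_flat = self.u.ravel(), self.v.ravel()
            res_u = np.abs(b_u - A_u @ u_flat).sum() / self._mom_norm
            res_v = np.abs(b_v - A_v @ v_flat).sum() / self._mom_norm
            # continuity residual: mass imbalance of the latest uncorrected
            # (Rhie-Chow) fluxes, i.e. what pressure correction had to fix
            res_m = self._last_mass_res
            self.history.append((self.n_iter, res_m, res_u, res_v))
            if log is not None:
                log.write(f"{self.n_iter} {res_m:.6e} {res_u:.6e} {res_v:.6e}\n")

            if not (np.isfinite(res_u) and np.isfinite(res_v) and np.isfinite(res_m)):
                raise NumericalBreakdownError(
                    f"non-finite residual at iteration {self.n_iter}",
                    residual_history=np.array(self.history),
                )
            if (
                res_m < cfg.tol_mass
                and res_u < cfg.tol_mom
                and res_v < cfg.tol_mom
                and self.n_iter > 1
            ):
                self.converged = True
                break

            # relax and solve momentum
            du = diag_u / alpha
            dv = diag_v / alpha
            bu = b_u + ((du - diag_u) * self.u).ravel()
            bv = b_v + ((dv - diag_v) * self.v).ravel()
            aW, aE, aS, aN = self._coef
            A_u = self._build_matrix(du, aW, aE, aS, aN)
            A_v = self._build_matrix(dv, aW, aE, aS, aN)
            self.u = splu(A_u).solve(bu).reshape(self.nx, self.nr)
            self.v = splu(A_v).solve(bv).reshape(self.nx, self.nr)
            if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
                raise NumericalBreakdownError(
                    f"non-finite velocity at iteration {self.n_iter}",
                    residual_history=np.array(self.history),
                )

            self._rAU = self.vol / du
            self._rhie_chow_fluxes(self._rAU)
            self.pressure_correction()
        return self.converged

    def as_flow_field(self) -> FlowField:
        # final viscosity: exact fixed-point evaluation on the final field
        self._update_viscosity(relax=1.0)
        gpx, gpr = self.pressure_gradient(self.p)
        return FlowField(
            grid=self.grid,
            rheology=self.rheology,
            bc=self.bc,
            u=self.u.copy(),
            v=self.v.copy(),
            p=self.p.copy(),
            mu_eff=self.mu.copy(),
            Fx=self.Fx.copy(),
            Fr=self.Fr.copy(),
            grad_p=(gpx.copy(), gpr.copy()),
            residual_history=np.array(self.history, dtype=float),
            converged=self.converged,
            n_iter=self.n_iter,
        )


def solve_steady(
    grid: AxisymmetricGrid,
    rheology: RheologyModel,
    bc: BoundaryConditions,
    cfg: Optional[NumericsConfig] = None,
    initial: Optional[FlowField] = None,
    log_path=None,
) -> FlowField:
    """Solve the steady axisymmetric flow with the SIMPLE algorithm.

    ``initial`` may be a :class:`FlowField` from a coarser grid of the same
    geometry; its fields are interpolated in computational coordinates for
    a warm start (grid sequencing).

    Raises
    ------
    ConvergenceError
        If the residual tolerances are not met within ``cfg.max_iter``
        (and ``cfg.raise_on_fail``); the exception carries the residual
        history.
    """
    cfg = cfg if cfg is not None else NumericsConfig()
    solver = SimpleSolver(grid, rheology, bc, cfg)
    if initial is not None:
        u, v, p = _interp_field_to_grid(initial, grid)
        solver.set_field(u=u, v=v, p=p)

    log = open(log_path, "w") if log_path is not None else None
    try:
        converged = solver.iterate(log=log)
    finally:
        if log is not None:
            log.close()
    if not converged and cfg.raise_on_fail:
        hist = np.array(solver.history)
        raise ConvergenceError(
            f"SIMPLE did not converge in {solver.n_iter} iterations "
            f"(last residuals mass={hist[-1, 1]:.3e}, u={hist[-1, 2]:.3e}, "
            f"v={hist[-1, 3]:.3e})",
            residual_history=hist,
        )
    return solver.as_flow_field()


def _comp_coords(grid: AxisymmetricGrid):
    """Computational coordinates (column x-centers, radial fractions)."""
    xcol = 0.5 * (grid.x_faces[:-1] + grid.x_faces[1:])
    fr = grid.r_frac_faces
    fc = 0.5 * (fr[:-1] + fr[1:])
    return xcol, fc


def _interp_field_to_grid(field: FlowField, grid: AxisymmetricGrid):
    """Interpolate (u, v, p) between structured grids of the same geometry."""
    from scipy.interpolate import RegularGridInterpolator

    xs, fs = _comp_coords(field.grid)
    xd, fd = _comp_coords(grid)
    Xd, Fd = np.meshgrid(xd, fd, indexing="ij")
    pts = np.stack([Xd.ravel(), Fd.ravel()], axis=1)
    out = []
    for arr in (field.u, field.v, field.p):
        itp = RegularGridInterpolator(
            (xs, fs), arr, bounds_error=False, fill_value=None, method="linear"
        )
        out.append(itp(pts).reshape(grid.nx, grid.nr))
    return out


# ----------------------------------------------------------------------
# module-level wrappers for the individual SIMPLE stages
# ----------------------------------------------------------------------
def momentum_assembly(grid, rheology, bc, cfg=None, u=None, v=None, p=None):
    """Assemble the linearized momentum systems about a given field state.

    Convenience wrapper building a fresh :class:`SimpleSolver`; returns
    ``(A_u, b_u, A_v, b_v)``.  Matrix dimensions equal the number of cells.
    """
    s = SimpleSolver(grid, rheology, bc, cfg)
    if u is not None or v is not None or p is not None:
        s.set_field(u=u, v=v, p=p)
    s._update_viscosity(relax=1.0)
    A_u, b_u, A_v, b_v, _, _ = s.momentum_assembly()
    return A_u, b_u, A_v, b_v


def pressure_correction(solver: SimpleSolver):
    """Apply one SIMPLE pressure-correction step to a prepared solver.

    The solver must have current Rhie–Chow fluxes (i.e. be mid-iteration);
    returns the pre-correction normalized mass residual.
    """
    return solver.pressure_correction()
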