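"""Hemodynamic metric extraction from converged flow fields.

Quantities reported for each case, following the conventions of the
stenosis-hemodynamics literature:

* **Wall shear stress (WSS)** — tangential viscous traction on the wall,
  ``tau_w = mu_w * du_t/dn`` evaluated at every wall face from the
  wall-normal gradient of the wall-tangential velocity; for a Carreau
  fluid ``mu_w`` is evaluated at the wall shear rate.  Profiles are
  reported as magnitudes against axial position; the *signed* stress is
  used to locate separation/reattachment.
* **Wall pressure** — cell pressures extrapolated to the wall with the
  cell pressure gradient, gauge-shifted so the sample at ``x = 9R`` is
  zero; the pressure drop is taken over the reporting window
  ``[-3R, 9R]``.
* **Separation-vortex length** — distance between the wall separation
  and reattachment points (sign changes of the signed wall shear
  downstream of the throat, sub-cell linear interpolation), expressed in
  units of ``R``; zero when the wall shear never changes sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import OutOfDomainError, StaleFieldError
from .rheology import viscosity
from .solver import FlowField

__all__ = [
    "HemodynamicSummary",
    "wall_shear_stress",
    "wall_pressure_profile",
    "pressure_drop",
    "vortex_length",
    "poiseuille_sensitivity_check",
    "summarize",
]


@dataclass(frozen=True)
class HemodynamicSummary:
    """Per-case scalar metrics plus the wall profiles they derive from."""

    eta: float
    rheology: str
    vortex_length_over_R: float
    separation_x: Optional[float]       # [m]; None when no vortex
    reattachment_x: Optional[float]
    n_recirculation_zones: int
    delta_p: float                      # wall pressure drop over the window [Pa]
    wss_peak: float                     # [Pa]
    wss_peak_x: float                   # [m]
    wall_x: np.ndarray = field(repr=False)
    wall_pressure_x: np.ndarray = field(repr=False)
    wall_pressure: np.ndarray = field(repr=False)
    wss_profile: np.ndarray = field(repr=False)          # magnitudes
    wss_signed: np.ndarray = field(repr=False)

    def to_record(self) -> dict:
        return {
            "eta": self.eta,
            "rheology": self.rheology,
            "vortex_length_over_R": self.vortex_length_over_R,
            "separation_x_mm": None if self.separation_x is None else 1e3 * self.separation_x,
            "reattachment_x_mm": None if self.reattachment_x is None else 1e3 * self.reattachment_x,
            "n_recirculation_zones": self.n_recirculation_zones,
            "delta_p_Pa": self.delta_p,
            "wss_peak_Pa": self.wss_peak,
            "wss_peak_x_mm": 1e3 * self.wss_peak_x,
        }


def _require_converged(f: FlowField) -> None:
    if not f.converged:
        raise StaleFieldError(
            "flow field is not converged; refusing to extract metrics "
            "(pass a converged FlowField)"
        )


def _wall_geometry(f: FlowField):
    g = f.grid
    Swx, Swr = g.jface_Sx[:, -1], g.jface_Sr[:, -1]
    Sw = np.hypot(Swx, Swr)
    dbx = g.jface_xc[:, -1] - g.xc[:, -1]
    dbr = g.jface_rc[:, -1] - g.rc[:, -1]
    dn = (Swx * dbx + Swr * dbr) / Sw            # centroid-to-wall normal distance
    tx, tr = Swr / Sw, -Swx / Sw                 # wall tangent, +x oriented
    xw = g.jface_xc[:, -1]
    return xw, dn, tx, tr, dbx, dbr


def wall_shear_stress(field: FlowField, signed: bool = False):
    """WSS profile ``(x, tau_w)`` at the wall-face centers.

    ``tau_w`` is the magnitude by default; ``signed=True`` returns the
    tangential (+x oriented) component whose sign changes mark flow
    separation and reattachment.
    """
    _require_converged(field)
    xw, dn, tx, tr, _, _ = _wall_geometry(field)
    ut = field.u[:, -1] * tx + field.v[:, -1] * tr
    gdot_w = np.abs(ut) / dn
    if field.rheology.kind == "newtonian":
        mu_w = np.full_like(gdot_w, field.rheology.mu)
    else:
        mu_w = viscosity(field.rheology, gdot_w)
    tau = mu_w * ut / dn
    return (xw, tau) if signed else (xw, np.abs(tau))


def _default_window(field: FlowField):
    R = field.grid.geom.R
    return (-3.0 * R, 9.0 * R)


def wall_pressure_profile(field: FlowField, window=None):
    """Wall pressure samples ``(x, p)`` over ``window``, gauged to 0 at its end.

    Cell-row pressures are extrapolated to the wall using the converged
    cell pressure gradient; the window endpoints are obtained by linear
    interpolation between wall-face centers and appended as samples, so
    the final sample (at ``x = 9R`` by default) is exactly zero.
    """
    _require_converged(field)
    lo, hi = window if window is not None else _default_window(field)
    xw, _, _, _, dbx, dbr = _wall_geometry(field)
    if lo < field.grid.x_faces[0] or hi > field.grid.x_faces[-1] or lo >= hi:
        raise OutOfDomainError(f"window [{lo}, {hi}] outside grid extent")
    gpx, gpr = field.grad_p
    pw = field.p[:, -1] + gpx[:, -1] * dbx + gpr[:, -1] * dbr
    inside = (xw > lo) & (xw < hi)
    xs = np.concatenate(([lo], xw[inside], [hi]))
    ps = np.concatenate(([np.interp(lo, xw, pw)], pw[inside], [np.interp(hi, xw, pw)]))
    return xs, ps - ps[-1]


def pressure_drop(field: FlowField, window=None) -> float:
    """Wall pressure drop ``p(window start) - p(window end)`` [Pa]."""
    xs, ps = wall_pressure_profile(field, window)
    return float(ps[0] - ps[-1])


def vortex_length(field: FlowField):
    """Primary post-stenotic recirculation bubble from wall-shear sign changes.

    Returns ``(length_over_R, separation_x, reattachment_x, n_zones)``;
    the positions are ``None`` and the length 0.0 when the signed wall
    shear never changes sign downstream of the throat.  With multiple
    recirculation zones the longest one is returned and the count flags it.
    """
    _require_converged(field)
    xw, tau = wall_shear_stress(field, signed=True)
    R = field.grid.geom.R
    # search strictly downstream of the throat (x > 0)
    mask = xw[:-1] > 0.0
    flips = np.where(mask & (tau[:-1] * tau[1:] < 0.0))[0]
    if flips.size == 0:
        return 0.0, None, None, 0
    x_cross = xw[flips] - tau[flips] * (xw[flips + 1] - xw[flips]) / (
        tau[flips + 1] - tau[flips]
    )
    # separation: + -> -, reattachment: - -> +
    seps = x_cross[tau[flips] > 0.0]
    reats = x_cross[tau[flips] < 0.0]
    # a bubble attached right at the throat may separate at x <= 0: then the
    # first crossing is a reattachment; take the throat as separation point
    if reats.size > 0 and (seps.size == 0 or reats[0] < seps[0]):
        seps = np.concatenate(([0.0], seps))
    zones = []
    for s in seps:
        after = reats[reats > s]
        if after.size:
            zones.append((s, after[0]))
    if not zones:
        return 0.0, None, None, 0
    lengths = [b - a for a, b in zones]
    k = int(np.argmax(lengths))
    sep, reat = zones[k]
    return float(lengths[k] / R), float(sep), float(reat), len(zones)


def poiseuille_sensitivity_check(delta_D_over_D: float) -> float:
    """Linearized sensitivity of the Poiseuille pressure drop to diameter.

    At fixed flow rate ``dp ~ D**-4``, so a small relative diameter change
    ``dD/D`` produces ``d(dp)/dp = -4 dD/D`` — narrowing raises the drop.
    """
    return -4.0 * float(delta_D_over_D)


def summarize(field: FlowField, window=None) -> HemodynamicSummary:
    """Extract the full per-case metric record from a converged field."""
    _require_converged(field)
    lo, hi = window if window is not None else _default_window(field)
    xw, tau_signed = wall_shear_stress(field, signed=True)
    tau_abs = np.abs(tau_signed)
    xs, ps = wall_pressure_profile(field, (lo, hi))
    dp = float(ps[0] - ps[-1])
    L, sep, reat, nz = vortex_length(field)
    inside = (xw >= lo) & (xw <= hi)
    k = int(np.argmax(tau_abs * inside))
    return HemodynamicSummary(
        eta=field.grid.geom.eta,
        rheology=field.rheology.kind,
        vortex_length_over_R=L,
        separation_x=sep,
        reattachment_x=reat,
        n_recirculation_zones=nz,
        delta_p=dp,
        wss_peak=float(tau_abs[k]),
        wss_peak_x=float(xw[k]),
        wall_x=xw.copy(),
        wall_pressure_x=xs,
        wall_pressure=ps,
        wss_profile=tau_abs,
        wss_signed=tau_signed,
    )
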