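"""Parameterized cosine-stenosis tube geometry.

An idealized stenosed artery is modelled as a rigid axisymmetric tube of
radius ``R`` whose wall is constricted over an axial length ``Ls`` by a
smooth cosine-shaped bump reaching a minimum (throat) radius ``Rt`` at
``x = 0``.  Severity is quantified by the area-based stenosis degree

    eta = 1 - (Rt / R)**2,

i.e. the fraction of the normal lumen cross-section blocked at the throat.
The wall profile is

    r_w(x) = R - (R - Rt)/2 * (1 + cos(2*pi*x/Ls))   for |x| <= Ls/2,
    r_w(x) = R                                        otherwise,

which is C1-continuous at the shoulders ``x = +-Ls/2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidGeometryError, OutOfDomainError

__all__ = [
    "StenosisGeometry",
    "stenosis_degree",
    "throat_radius_from_degree",
    "wall_radius",
]


def stenosis_degree(R: float, Rt: float) -> float:
    """Area-based degree of stenosis ``1 - (Rt/R)**2``.

    Parameters
    ----------
    R : float
        Unobstructed vessel radius [m].
    Rt : float
        Throat (minimum lumen) radius [m]; requires ``0 < Rt <= R``.
    """
    if not (R > 0.0):
        raise InvalidGeometryError(f"vessel radius must be positive, got R={R!r}")
    if not (0.0 < Rt <= R):
        raise InvalidGeometryError(
            f"throat radius must satisfy 0 < Rt <= R, got Rt={Rt!r}, R={R!r}"
        )
    return 1.0 - (Rt / R) ** 2


def throat_radius_from_degree(R: float, eta: float) -> float:
    """Invert :func:`stenosis_degree`: ``Rt = R*sqrt(1 - eta)`` for ``eta in [0, 1)``."""
    if not (R > 0.0):
        raise InvalidGeometryError(f"vessel radius must be positive, got R={R!r}")
    if not (0.0 <= eta < 1.0):
        raise InvalidGeometryError(f"stenosis degree must lie in [0, 1), got {eta!r}")
    return R * float(np.sqrt(1.0 - eta))


@dataclass(frozen=True)
class StenosisGeometry:
    """Axisymmetric cosine-stenosed tube.

    Attributes
    ----------
    R : float
        Vessel radius [m].
    Rt : float
        Throat radius [m].
    Ls : float
        Axial length of the constricted region [m]; the bump occupies
        ``|x| <= Ls/2`` with the throat at ``x = 0``.
    x_inlet, x_outlet : float
        Axial extent of the computational domain [m];
        ``x_inlet < -Ls/2 < Ls/2 < x_outlet``.
    """

    R: float
    Rt: float
    Ls: float
    x_inlet: float
    x_outlet: float

    def __post_init__(self) -> None:
        stenosis_degree(self.R, self.Rt)  # validates R, Rt
        if not (self.Ls > 0.0):
            raise InvalidGeometryError(f"stenosis length must be positive, got {self.Ls!r}")
        if not (self.x_inlet < -0.5 * self.Ls and self.x_outlet > 0.5 * self.Ls):
            raise InvalidGeometryError(
                "domain must bracket the stenosis: need "
                f"x_inlet < {-0.5 * self.Ls} < {0.5 * self.Ls} < x_outlet, "
                f"got [{self.x_inlet}, {self.x_outlet}]"
            )

    @classmethod
    def from_degree(
        cls,
        R: float,
        eta: float,
        Ls: float,
        x_inlet: float,
        x_outlet: float,
    ) -> "StenosisGeometry":
        """Build a geometry from the stenosis degree instead of the throat radius."""
        return cls(R=R, Rt=throat_radius_from_degree(R, eta), Ls=Ls,
                   x_inlet=x_inlet, x_outlet=x_outlet)

    @property
    def eta(self) -> float:
        """Degree of stenosis ``1 - (Rt/R)**2``."""
        return stenosis_degree(self.R, self.Rt)

    @property
    def D(self) -> float:
        """Vessel diameter ``2R`` [m]."""
        return 2.0 * self.R

    def wall_radius(self, x):
        """Lumen radius of the wall at axial position(s) ``x`` [m]."""
        return wall_radius(self, x)


def wall_radius(geom: StenosisGeometry, x):
    """Cosine wall profile ``r_w(x)``; accepts scalars or arrays.

    Raises
    ------
    OutOfDomainError
        If any ``x`` lies outside ``[x_inlet, x_outlet]`` (beyond a tiny
        floating-point slack).
    """
    xa = np.asarray(x, dtype=float)
    slack = 1e-9 * max(abs(geom.x_inlet), abs(geom.x_outlet), geom.R)
    if np.any(xa < geom.x_inlet - slack) or np.any(xa > geom.x_outlet + slack):
        raise OutOfDomainError(
            f"x outside [{geom.x_inlet}, {geom.x_outlet}]: "
            f"range [{xa.min()}, {xa.max()}]"
        )
    depth = 0.5 * (geom.R - geom.Rt)
    rw = np.where(
        np.abs(xa) <= 0.5 * geom.Ls,
        geom.R - depth * (1.0 + np.cos(2.0 * np.pi * xa / geom.Ls)),
        geom.R,
    )
    if np.isscalar(x) or xa.ndim == 0:
        return float(rw)
    return rw
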