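"""Constitutive models for blood: constant-viscosity Newtonian and Carreau.

The Carreau law interpolates between a zero-shear plateau ``mu_0`` and an
infinite-shear plateau ``mu_inf``:

    mu(gdot) = mu_inf + (mu_0 - mu_inf) * (1 + (lambda_t*gdot)**2)**((n-1)/2)

with time constant ``lambda_t`` [s] and power index ``0 < n < 1``
(shear-thinning).  Default parameters are a standard whole-blood fit:
mu_inf = 3.45 mPa.s (plasma), mu_0 = 56 mPa.s, lambda_t = 3.313 s,
n = 0.3568, used with density rho = 1050 kg/m^3.

The scalar shear-rate measure for axisymmetric (x, r) flow is the
generalized second invariant

    gdot = sqrt(2 D:D),
    D:D  = (du/dx)^2 + (dv/dr)^2 + (v/r)^2 + 0.5*(du/dr + dv/dx)^2,

which reduces to the imposed gradient in simple shear and includes the
hoop component ``v/r`` (evaluated as ``dv/dr`` on the axis, its limit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "RheologyModel",
    "viscosity",
    "shear_rate",
    "BLOOD_DENSITY",
    "PLASMA_VISCOSITY",
    "CARREAU_BLOOD",
    "NEWTONIAN_BLOOD",
]

#: Whole-blood density used throughout the reference cases [kg/m^3].
BLOOD_DENSITY = 1050.0

#: Plasma viscosity [Pa.s]; also the Newtonian blood viscosity consistent
#: with Re = rho*Um*D/mu = 300 at the reference flow conditions.
PLASMA_VISCOSITY = 0.00345


@dataclass(frozen=True)
class RheologyModel:
    """Tagged constitutive law.

    ``kind`` is ``"newtonian"`` (uses ``mu``) or ``"carreau"`` (uses
    ``mu_inf``, ``mu_0``, ``lambda_t``, ``n_exp``).
    """

    kind: str
    mu: float | None = None
    mu_inf: float | None = None
    mu_0: float | None = None
    lambda_t: float | None = None
    n_exp: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "newtonian":
            if self.mu is None or not self.mu > 0.0:
                raise ConfigurationError(f"newtonian model needs mu > 0, got {self.mu!r}")
        elif self.kind == "carreau":
            if None in (self.mu_inf, self.mu_0, self.lambda_t, self.n_exp):
                raise ConfigurationError("carreau model needs mu_inf, mu_0, lambda_t, n_exp")
            if not (0.0 < self.mu_inf < self.mu_0):
                raise ConfigurationError(
                    f"carreau needs 0 < mu_inf < mu_0, got {self.mu_inf!r}, {self.mu_0!r}"
                )
            if self.lambda_t < 0.0:
                raise ConfigurationError(f"carreau time constant must be >= 0, got {self.lambda_t!r}")
            if not (0.0 < self.n_exp < 1.0):
                raise ConfigurationError(f"carreau power index must lie in (0,1), got {self.n_exp!r}")
        else:
            raise ConfigurationError(f"unknown rheology kind {self.kind!r}")

    @classmethod
    def newtonian(cls, mu: float = PLASMA_VISCOSITY) -> "RheologyModel":
        return cls(kind="newtonian", mu=mu)

    @classmethod
    def carreau(
        cls,
        mu_inf: float = PLASMA_VISCOSITY,
        mu_0: float = 0.056,
        lambda_t: float = 3.313,
        n_exp: float = 0.3568,
    ) -> "RheologyModel":
        return cls(kind="carreau", mu_inf=mu_inf, mu_0=mu_0,
                   lambda_t=lambda_t, n_exp=n_exp)

    @property
    def mu_high_shear(self) -> float:
        """Viscosity in the infinite-shear limit (equals ``mu`` for Newtonian)."""
        return self.mu if self.kind == "newtonian" else self.mu_inf

    def label(self) -> str:
        return self.kind


#: Default blood models for the Re = 300 reference cases.
CARREAU_BLOOD = RheologyModel.carreau()
NEWTONIAN_BLOOD = RheologyModel.newtonian()


def viscosity(model: RheologyModel, gamma_dot):
    """Dynamic viscosity [Pa.s] at shear rate(s) ``gamma_dot`` [1/s].

    Newtonian models return ``mu`` for any shear rate; Carreau models are
    continuous, strictly decreasing in ``gamma_dot`` and bounded in
    ``(mu_inf, mu_0]``.  Negative shear rates are rejected (the measure
    returned by :func:`shear_rate` is nonnegative by construction).
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0.0):
        raise ValueError("shear rate must be nonnegative")
    if model.kind == "newtonian":
        out = np.full_like(g, model.mu)
    else:
        out = model.mu_inf + (model.mu_0 - model.mu_inf) * (
            1.0 + (model.lambda_t * g) ** 2
        ) ** (0.5 * (model.n_exp - 1.0))
    if np.isscalar(gamma_dot) or out.ndim == 0:
        return float(out)
    return out


def shear_rate(du_dx, du_dr, dv_dx, dv_dr, v, r):
    """Generalized shear rate ``sqrt(2 D:D)`` [1/s] for axisymmetric flow.

    All arguments broadcast; ``r`` may contain zeros (on the axis the hoop
    strain ``v/r`` is replaced by its limit ``dv/dr``).
    """
    du_dx, du_dr, dv_dx, dv_dr, v, r = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (du_dx, du_dr, dv_dx, dv_dr, v, r))
    )
    on_axis = r <= 0.0
    hoop = np.where(on_axis, dv_dr, v / np.where(on_axis, 1.0, r))
    dd = du_dx**2 + dv_dr**2 + hoop**2 + 0.5 * (du_dr + dv_dx) ** 2
    out = np.sqrt(2.0 * dd)
    if out.ndim == 0:
        return float(out)
    return out
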