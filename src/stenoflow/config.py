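"""YAML case configuration.

Example
-------
::

    geometry:
      R_mm: 5.0
      eta: 0.75          # or Rt_mm: 2.5
      Ls_over_R: 4.0
      x_inlet_over_R: -6.0
      x_outlet_over_R: 30.0
    grid:
      n_axial: 192
      n_radial: 40
      radial_beta: 2.2
      stenosis_refine: 4.0
      wake_refine: 2.2
    flow:
      Q_L_per_min: 0.465
      rho: 1050.0
      inlet_profile: fully_developed
    rheology:
      model: carreau     # or newtonian
      # optional overrides: mu, mu_inf, mu_0, lambda_t, n_exp
    numerics:
      relax_u: 0.7
      relax_p: 0.3
      tol_mass: 1.0e-6
      tol_mom: 1.0e-6
      max_iter: 5000
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .cases import CaseSpec
from .errors import ConfigurationError
from .geometry import stenosis_degree
from .grid import GridClustering
from .rheology import RheologyModel
from .solver import NumericsConfig

__all__ = ["case_from_config", "load_case"]


def _rheology_from(section: dict) -> RheologyModel:
    model = section.get("model", "carreau")
    if model == "newtonian":
        kwargs = {k: section[k] for k in ("mu",) if k in section}
        return RheologyModel.newtonian(**kwargs)
    if model == "carreau":
        kwargs = {
            k: section[k]
            for k in ("mu_inf", "mu_0", "lambda_t", "n_exp")
            if k in section
        }
        return RheologyModel.carreau(**kwargs)
    raise ConfigurationError(f"unknown rheology model {model!r}")


def case_from_config(cfg: dict, label: str = "") -> CaseSpec:
    """Build a fully resolved :class:`~stenoflow.cases.CaseSpec` from a dict."""
    geo = dict(cfg.get("geometry", {}))
    gridc = dict(cfg.get("grid", {}))
    flow = dict(cfg.get("flow", {}))
    rheo = dict(cfg.get("rheology", {}))
    nums = dict(cfg.get("numerics", {}))

    R = 1e-3 * float(geo.get("R_mm", 5.0))
    if "eta" in geo and "Rt_mm" in geo:
        raise ConfigurationError("specify either eta or Rt_mm, not both")
    if "Rt_mm" in geo:
        eta = stenosis_degree(R, 1e-3 * float(geo["Rt_mm"]))
    else:
        eta = float(geo.get("eta", 0.0))

    clustering_keys = (
        "radial_beta", "stenosis_refine", "wake_refine",
        "wake_end_over_R", "ramp_over_R",
    )
    clustering = GridClustering(
        **{k: float(gridc[k]) for k in clustering_keys if k in gridc}
    )
    numerics = NumericsConfig(
        **{k: v for k, v in nums.items() if k in NumericsConfig.__dataclass_fields__}
    )

    kwargs = dict(
        eta=eta,
        rheology=_rheology_from(rheo),
        R=R,
        clustering=clustering,
        numerics=numerics,
    )
    if label:
        kwargs["label"] = label
    for src_key, dst_key, scale in (
        ("Ls_over_R", "Ls_over_R", 1.0),
        ("x_inlet_over_R", "x_inlet_over_R", 1.0),
        ("x_outlet_over_R", "x_outlet_over_R", 1.0),
    ):
        if src_key in geo:
            kwargs[dst_key] = scale * float(geo[src_key])
    if "n_axial" in gridc:
        kwargs["n_axial"] = int(gridc["n_axial"])
    if "n_radial" in gridc:
        kwargs["n_radial"] = int(gridc["n_radial"])
    if "Q_L_per_min" in flow:
        kwargs["Q"] = float(flow["Q_L_per_min"]) * 1e-3 / 60.0
    if "rho" in flow:
        kwargs["rho"] = float(flow["rho"])
    if "inlet_profile" in flow:
        kwargs["inlet_profile"] = str(flow["inlet_profile"])
    return CaseSpec(**kwargs)


def load_case(path, label: str = "") -> CaseSpec:
    """Load a case configuration from a YAML file."""
    with open(Path(path)) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(cfg)}")
    return case_from_config(cfg, label=label)
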