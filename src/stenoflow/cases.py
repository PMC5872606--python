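"""Reference case suite: five stenosis degrees x two rheologies at Re = 300.

The standard conditions shared by all cases: vessel radius R = 5 mm
(D = 10 mm), stenosis length Ls = 4R, steady inflow Q = 0.465 L/min
(mean velocity Um = 0.0986 m/s), blood density rho = 1050 kg/m^3.  With
the plasma viscosity mu = 3.45 mPa.s this gives Re = rho*Um*D/mu = 300.
Stenosis degrees eta in {0, 0.25, 0.5, 0.625, 0.75} are each solved with
the Newtonian (plasma-viscosity) and Carreau blood models.

The computational domain runs from x = -6R to x = 30R so that even the
longest recirculation bubble (about 14R for the severest Newtonian case)
reattaches far upstream of the outlet; metrics are reported over the
window [-3R, 9R].
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StenoflowError
from .geometry import StenosisGeometry
from .grid import AxisymmetricGrid, GridClustering, generate_grid
from .metrics import HemodynamicSummary, summarize
from .rheology import BLOOD_DENSITY, RheologyModel
from .solver import BoundaryConditions, FlowField, NumericsConfig, solve_steady

__all__ = [
    "CaseSpec",
    "SuiteResult",
    "build_reference_cases",
    "run_case",
    "run_suite",
    "grid_convergence_study",
    "REFERENCE_ETAS",
    "DEFAULT_RESOLUTION",
]

#: Stenosis degrees of the reference study.
REFERENCE_ETAS = (0.0, 0.25, 0.5, 0.625, 0.75)

#: Default grid resolution (axial x radial cells).  Chosen from the grid
#: convergence study: all summary metrics change by well under 1% when the
#: resolution is doubled (see docs/methods.md).
DEFAULT_RESOLUTION = (160, 32)

#: Reference flow rate: 0.465 L/min in m^3/s.
REFERENCE_Q = 0.465e-3 / 60.0


@dataclass(frozen=True)
class CaseSpec:
    """Fully resolved description of one simulation case."""

    eta: float
    rheology: RheologyModel
    label: str = ""
    R: float = 5e-3
    Ls_over_R: float = 4.0
    x_inlet_over_R: float = -6.0
    x_outlet_over_R: float = 30.0
    Q: float = REFERENCE_Q
    rho: float = BLOOD_DENSITY
    n_axial: int = DEFAULT_RESOLUTION[0]
    n_radial: int = DEFAULT_RESOLUTION[1]
    clustering: GridClustering = field(default_factory=GridClustering)
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    inlet_profile: str = "fully_developed"

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta < 1.0):
            raise ConfigurationError(f"eta must lie in [0,1), got {self.eta!r}")
        if not self.label:
            object.__setattr__(self, "label", f"eta{self.eta:g}_{self.rheology.kind}")

    def geometry(self) -> StenosisGeometry:
        return StenosisGeometry.from_degree(
            self.R,
            self.eta,
            self.Ls_over_R * self.R,
            self.x_inlet_over_R * self.R,
            self.x_outlet_over_R * self.R,
        )

    def grid(self, refine: int = 1) -> AxisymmetricGrid:
        return generate_grid(
            self.geometry(), refine * self.n_axial, refine * self.n_radial,
            self.clustering,
        )

    def boundary_conditions(self) -> BoundaryConditions:
        return BoundaryConditions(Q=self.Q, rho=self.rho,
                                  inlet_profile=self.inlet_profile)

    def mean_velocity(self) -> float:
        return self.Q / (np.pi * self.R**2)

    def reynolds(self) -> float:
        """Re based on vessel diameter and the high-shear (plasma) viscosity."""
        return self.rho * self.mean_velocity() * 2.0 * self.R / self.rheology.mu_high_shear

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "eta": self.eta,
            "rheology": self.rheology.kind,
            "R_mm": 1e3 * self.R,
            "Ls_over_R": self.Ls_over_R,
            "x_inlet_over_R": self.x_inlet_over_R,
            "x_outlet_over_R": self.x_outlet_over_R,
            "Q_L_per_min": self.Q * 60.0 * 1e3,
            "rho": self.rho,
            "n_axial": self.n_axial,
            "n_radial": self.n_radial,
            "inlet_profile": self.inlet_profile,
            "reynolds": self.reynolds(),
        }
        if self.rheology.kind == "carreau":
            d.update(
                mu_inf=self.rheology.mu_inf, mu_0=self.rheology.mu_0,
                lambda_t=self.rheology.lambda_t, n_exp=self.rheology.n_exp,
            )
        else:
            d.update(mu=self.rheology.mu)
        return d


def build_reference_cases(
    n_axial: Optional[int] = None,
    n_radial: Optional[int] = None,
    numerics: Optional[NumericsConfig] = None,
) -> list[CaseSpec]:
    """The ten standard cases: REFERENCE_ETAS x {newtonian, carreau}."""
    kwargs = {}
    if n_axial is not None:
        kwargs["n_axial"] = n_axial
    if n_radial is not None:
        kwargs["n_radial"] = n_radial
    if numerics is not None:
        kwargs["numerics"] = numerics
    models = (RheologyModel.newtonian(), RheologyModel.carreau())
    return [
        CaseSpec(eta=eta, rheology=m, **kwargs)
        for m in models
        for eta in REFERENCE_ETAS
    ]


@dataclass
class CaseResult:
    spec: CaseSpec
    field: Optional[FlowField]
    summary: Optional[HemodynamicSummary]
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass
class SuiteResult:
    """Ordered collection of per-case outcomes; failures are kept, not dropped."""

    results: list[CaseResult]

    def __len__(self) -> int:
        return len(self.results)

    @property
    def failures(self) -> list[CaseResult]:
        return [r for r in self.results if not r.ok]

    def to_frame(self) -> pd.DataFrame:
        """Summary table with the columns needed for the vortex-length and
        pressure-drop comparisons across eta and rheology."""
        rows = []
        for r in self.results:
            if r.ok:
                rec = r.summary.to_record()
                rec.update(label=r.spec.label, converged=r.field.converged,
                           n_iter=r.field.n_iter, error=None)
            else:
                rec = {"label": r.spec.label, "eta": r.spec.eta,
                       "rheology": r.spec.rheology.kind, "error": r.error}
            rows.append(rec)
        return pd.DataFrame(rows)


def run_case(
    spec: CaseSpec,
    initial: Optional[FlowField] = None,
    out_dir: Optional[Path] = None,
    refine: int = 1,
) -> tuple[FlowField, HemodynamicSummary]:
    """Solve one case and extract its hemodynamic summary.

    ``out_dir`` (optional) receives the residual log, the field CSV, the
    wall profiles and the resolved case manifest.
    """
    grid = spec.grid(refine=refine)
    log_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log_path = out_dir / "residuals.log"
    flow = solve_steady(
        grid, spec.rheology, spec.boundary_conditions(), spec.numerics,
        initial=initial, log_path=log_path,
    )
    summary = summarize(flow)
    if out_dir is not None:
        _write_case_outputs(spec, flow, summary, out_dir)
    return flow, summary


def _write_case_outputs(spec, flow, summary, out_dir: Path) -> None:
    (out_dir / "case.json").write_text(json.dumps(spec.to_dict(), indent=2))
    flow.to_dataframe().to_csv(out_dir / "field.csv", index=False)
    pd.DataFrame(
        {"x_mm": 1e3 * summary.wall_x, "wss_Pa": summary.wss_profile,
         "wss_signed_Pa": summary.wss_signed}
    ).to_csv(out_dir / "wss_profile.csv", index=False)
    pd.DataFrame(
        {"x_mm": 1e3 * summary.wall_pressure_x, "wall_p_Pa": summary.wall_pressure}
    ).to_csv(out_dir / "wall_pressure.csv", index=False)
    rec = summary.to_record()
    rec["converged"] = bool(flow.converged)
    rec["n_iter"] = int(flow.n_iter)
    (out_dir / "summary.json").write_text(json.dumps(rec, indent=2))


def run_suite(
    specs: Sequence[CaseSpec],
    out_dir: Optional[Path] = None,
) -> SuiteResult:
    """Run a sequence of independent cases, collecting results and failures.

    Cases are solved sequentially in the given order; each case is fully
    deterministic, so scheduling cannot change any result.  A failing case
    is recorded with its error message and the suite continues.
    """
    results: list[CaseResult] = []
    for spec in specs:
        case_dir = Path(out_dir) / spec.label if out_dir is not None else None
        try:
            flow, summary = run_case(spec, out_dir=case_dir)
            results.append(CaseResult(spec, flow, summary))
        except StenoflowError as exc:
            results.append(CaseResult(spec, None, None, error=f"{type(exc).__name__}: {exc}"))
        except Exception as exc:  # pragma: no cover - defensive
            results.append(
                CaseResult(spec, None, None,
                           error="".join(traceback.format_exception_only(exc)).strip())
            )
    suite = SuiteResult(results)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df = suite.to_frame()
        df.to_csv(out_dir / "suite_summary.csv", index=False)
        df.to_json(out_dir / "suite_summary.json", orient="records", indent=2)
    return suite


def grid_convergence_study(
    spec: CaseSpec,
    refinements: Sequence[int] = (1, 2),
    warm_start: bool = True,
) -> pd.DataFrame:
    """Solve ``spec`` at successive uniform refinements of its grid.

    Returns a table of (resolution, vortex length, pressure drop, WSS
    peak) with the relative change of each metric between successive
    levels.  Finer levels are warm-started from the interpolated coarser
    solution by default, which does not change the converged answer (the
    tolerances are identical) but saves iterations.
    """
    if len(refinements) < 2:
        raise ConfigurationError("need at least two refinement levels")
    rows = []
    prev_field = None
    prev = None
    for lvl in refinements:
        try:
            flow, summary = run_case(
                spec, initial=prev_field if warm_start else None, refine=int(lvl)
            )
        except StenoflowError as exc:
            rows.append({"refine": lvl, "n_axial": lvl * spec.n_axial,
                         "n_radial": lvl * spec.n_radial,
                         "failed": f"{type(exc).__name__}: {exc}"})
            prev_field, prev = None, None
            continue
        row = {
            "refine": lvl,
            "n_axial": lvl * spec.n_axial,
            "n_radial": lvl * spec.n_radial,
            "vortex_length_over_R": summary.vortex_length_over_R,
            "delta_p_Pa": summary.delta_p,
            "wss_peak_Pa": summary.wss_peak,
            "failed": None,
        }
        if prev is not None and prev.get("failed") is None:
            for key in ("vortex_length_over_R", "delta_p_Pa", "wss_peak_Pa"):
                ref = prev[key]
                row[f"rel_change_{key}"] = (
                    abs(row[key] - ref) / abs(ref) if ref != 0.0 else abs(row[key])
                )
        rows.append(row)
        prev_field, prev = flow, row
    return pd.DataFrame(rows)
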