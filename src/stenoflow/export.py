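"""Field and grid export helpers (CSV and legacy-ASCII VTK)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .grid import AxisymmetricGrid
from .solver import FlowField

__all__ = ["field_to_csv", "grid_to_vtk", "field_to_vtk"]


def field_to_csv(field: FlowField, path) -> None:
    """Cell-centered (x, r, u, v, p, mu_eff) table."""
    field.to_dataframe().to_csv(path, index=False)


def _vtk_header(grid: AxisymmetricGrid, title: str) -> list[str]:
    nxp, nrp = grid.nx + 1, grid.nr + 1
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {nxp} {nrp} 1",
        f"POINTS {nxp * nrp} double",
    ]
    x = np.broadcast_to(grid.x_faces[:, None], (nxp, nrp))
    r = grid.vertex_r
    for j in range(nrp):
        for i in range(nxp):
            lines.append(f"{x[i, j]:.9e} {r[i, j]:.9e} 0.0")
    return lines


def grid_to_vtk(grid: AxisymmetricGrid, path) -> None:
    """Write the meridional mesh as a legacy-ASCII VTK structured grid."""
    Path(path).write_text("\n".join(_vtk_header(grid, "stenoflow grid")) + "\n")


def field_to_vtk(field: FlowField, path) -> None:
    """Write the mesh plus cell data (u, v, p, mu_eff) in legacy-ASCII VTK."""
    grid = field.grid
    lines = _vtk_header(grid, "stenoflow flow field")
    lines.append(f"CELL_DATA {grid.n_cells}")
    for name, arr in (
        ("u", field.u), ("v", field.v), ("p", field.p), ("mu_eff", field.mu_eff)
    ):
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK structured order: x index fastest
        lines.extend(f"{val:.9e}" for val in arr.T.ravel())
    Path(path).write_text("\n".join(lines) + "\n")
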