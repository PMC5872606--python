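"""Boundary-fitted structured grids for the axisymmetric stenosed tube.

The mesh is a single structured block of quadrilaterals in the meridional
``(x, r)`` plane: axial face positions ``x_faces`` are shared by all rows,
and radial face positions are a fixed set of fractions of the *local* wall
radius, ``r = f_j * r_w(x)``.  Columns therefore follow the cosine wall
exactly, faces between columns are vertical segments, and faces between
rows are straight segments that tilt with the wall.

All "areas" and "volumes" carry the axisymmetric weight and are stored
per unit azimuthal radian: a face area is ``int r dl`` along the segment
and a cell volume is ``int r dA`` over the quad (multiply by ``2*pi`` for
the full revolution).  The bottom row of faces lies on the axis ``r = 0``
where the revolved area vanishes identically, which encodes the symmetry
condition without special-casing.

Grid nodes are clustered toward the wall (tanh stretching of the radial
fractions) and axially toward the stenosis and its wake (smoothed
piecewise density), since that is where the wall shear stress and the
separation/reattachment points must be resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .geometry import StenosisGeometry, wall_radius

__all__ = ["GridClustering", "AxisymmetricGrid", "generate_grid"]


@dataclass(frozen=True)
class GridClustering:
    """Stretching-law parameters for :func:`generate_grid`.

    radial_beta
        tanh stretching strength toward the wall; 0 gives uniform spacing,
        the default 2.2 makes the wall-adjacent cell about 0.11x the
        uniform spacing.
    stenosis_refine
        axial node-density multiplier inside ``|x| <= Ls``.
    wake_refine
        axial density multiplier in the post-stenotic wake
        ``Ls <= x <= wake_end_over_R * R`` where the recirculation bubble
        reattaches.
    ramp_over_R
        smoothing width of the density transitions, in units of ``R``.
    """

    radial_beta: float = 2.2
    stenosis_refine: float = 4.0
    wake_refine: float = 2.2
    wake_end_over_R: float = 14.0
    ramp_over_R: float = 1.0

    def __post_init__(self) -> None:
        if self.radial_beta < 0.0:
            raise ConfigurationError(f"radial_beta must be >= 0, got {self.radial_beta!r}")
        for name in ("stenosis_refine", "wake_refine", "wake_end_over_R", "ramp_over_R"):
            if not getattr(self, name) > 0.0:
                raise ConfigurationError(f"{name} must be positive")


def _radial_fractions(n_radial: int, beta: float) -> np.ndarray:
    j = np.linspace(0.0, 1.0, n_radial + 1)
    if beta < 1e-10:
        return j
    f = np.tanh(beta * j) / np.tanh(beta)
    f[0], f[-1] = 0.0, 1.0
    return f


def _axial_faces(geom: StenosisGeometry, n_axial: int, cl: GridClustering) -> np.ndarray:
    xs = np.linspace(geom.x_inlet, geom.x_outlet, 8193)
    ramp = cl.ramp_over_R * geom.R

    def box(a, b):
        return 0.5 * (np.tanh((xs - a) / ramp) - np.tanh((xs - b) / ramp))

    w = (
        1.0
        + (cl.stenosis_refine - 1.0) * box(-geom.Ls, geom.Ls)
        + (cl.wake_refine - 1.0) * box(geom.Ls, cl.wake_end_over_R * geom.R)
    )
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(xs))))
    targets = np.linspace(0.0, cum[-1], n_axial + 1)
    x_faces = np.interp(targets, cum, xs)
    x_faces[0], x_faces[-1] = geom.x_inlet, geom.x_outlet
    return x_faces


def _polygon_centroid(x, r):
    """Planar centroid and signed area of quads given CCW corner arrays.

    ``x, r`` have shape (4, ...) ordered bl, br, tr, tl.
    """
    xn, rn = np.roll(x, -1, axis=0), np.roll(r, -1, axis=0)
    cross = x * rn - xn * r
    area = 0.5 * np.sum(cross, axis=0)
    cx = np.sum((x + xn) * cross, axis=0) / (6.0 * area)
    cr = np.sum((r + rn) * cross, axis=0) / (6.0 * area)
    return cx, cr, area


@dataclass(frozen=True)
class AxisymmetricGrid:
    """Structured boundary-fitted mesh with axisymmetric metrics.

    Index convention: cells ``[i, j]`` with ``i`` axial (0 at the inlet)
    and ``j`` radial (0 at the axis).  i-faces (constant ``x``) have shape
    ``(nx+1, nr)`` and unit normal ``+x``; j-faces (between radial rows)
    have shape ``(nx, nr+1)`` with their area vector oriented toward
    larger ``r``.  Boundary tags follow from the structure: ``i=0`` inlet,
    ``i=nx`` outlet, ``j=0`` axis, ``j=nr`` wall.
    """

    geom: StenosisGeometry
    x_faces: np.ndarray          # (nx+1,)
    r_frac_faces: np.ndarray     # (nr+1,)
    clustering: GridClustering = field(default_factory=GridClustering)

    # derived metric arrays, filled in __post_init__
    xc: np.ndarray = field(init=False, repr=False)       # (nx, nr)
    rc: np.ndarray = field(init=False, repr=False)       # (nx, nr)
    vol: np.ndarray = field(init=False, repr=False)      # (nx, nr) per radian
    area_plan: np.ndarray = field(init=False, repr=False)  # (nx, nr) meridional
    vertex_r: np.ndarray = field(init=False, repr=False)   # (nx+1, nr+1)
    iface_S: np.ndarray = field(init=False, repr=False)    # (nx+1, nr) per radian
    iface_rc: np.ndarray = field(init=False, repr=False)   # (nx+1, nr)
    iface_plan: np.ndarray = field(init=False, repr=False)  # (nx+1, nr) planar span
    jface_Sx: np.ndarray = field(init=False, repr=False)   # (nx, nr+1) per radian
    jface_Sr: np.ndarray = field(init=False, repr=False)   # (nx, nr+1)
    jface_Px: np.ndarray = field(init=False, repr=False)   # planar vectors
    jface_Pr: np.ndarray = field(init=False, repr=False)
    jface_xc: np.ndarray = field(init=False, repr=False)
    jface_rc: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        x_faces = np.asarray(self.x_faces, dtype=float)
        fr = np.asarray(self.r_frac_faces, dtype=float)
        if x_faces.ndim != 1 or x_faces.size < 3 or np.any(np.diff(x_faces) <= 0.0):
            raise ConfigurationError("x_faces must be strictly increasing with >= 3 entries")
        if (
            fr.ndim != 1
            or fr.size < 3
            or np.any(np.diff(fr) <= 0.0)
            or abs(fr[0]) > 1e-14
            or abs(fr[-1] - 1.0) > 1e-12
        ):
            raise ConfigurationError("r_frac_faces must increase strictly from 0 to 1")
        object.__setattr__(self, "x_faces", x_faces)
        object.__setattr__(self, "r_frac_faces", fr)

        wall_r = wall_radius(self.geom, x_faces)           # (nx+1,)
        vert_r = np.outer(wall_r, fr)                      # (nx+1, nr+1)
        object.__setattr__(self, "vertex_r", vert_r)

        xl = x_faces[:-1][:, None]          # (nx, 1)
        xr = x_faces[1:][:, None]
        rbl = vert_r[:-1, :-1]              # bottom-left radii (nx, nr)
        rbr = vert_r[1:, :-1]
        rtr = vert_r[1:, 1:]
        rtl = vert_r[:-1, 1:]

        # planar centroid / area (CCW order: bl, br, tr, tl)
        qx = np.stack([np.broadcast_to(xl, rbl.shape), np.broadcast_to(xr, rbl.shape),
                       np.broadcast_to(xr, rbl.shape), np.broadcast_to(xl, rbl.shape)])
        qr = np.stack([rbl, rbr, rtr, rtl])
        cx, cr, area = _polygon_centroid(qx, qr)
        if np.any(area <= 0.0):
            raise ConfigurationError("degenerate cell: non-positive planar area")
        object.__setattr__(self, "xc", cx)
        object.__setattr__(self, "rc", cr)
        object.__setattr__(self, "area_plan", area)

        # per-radian volume: int r dA = dx/6 * [(top) - (bottom)] quadratic sums
        dx = xr - xl
        top = rtl**2 + rtl * rtr + rtr**2
        bot = rbl**2 + rbl * rbr + rbr**2
        vol = dx / 6.0 * (top - bot)
        if np.any(vol <= 0.0):
            raise ConfigurationError("degenerate cell: non-positive volume")
        object.__setattr__(self, "vol", vol)

        # i-faces: vertical segments at x_faces[i] spanning vert_r[i, j:j+2]
        rb = vert_r[:, :-1]
        rt = vert_r[:, 1:]
        object.__setattr__(self, "iface_S", 0.5 * (rt**2 - rb**2))
        object.__setattr__(self, "iface_rc", 0.5 * (rt + rb))
        object.__setattr__(self, "iface_plan", rt - rb)

        # j-faces: straight segments from (x_i, f_j*w_i) to (x_{i+1}, f_j*w_{i+1})
        dxf = np.diff(x_faces)[:, None]                    # (nx, 1)
        r1 = vert_r[:-1, :]                                # (nx, nr+1)
        r2 = vert_r[1:, :]
        drf = r2 - r1
        rmid = 0.5 * (r1 + r2)
        object.__setattr__(self, "jface_Sx", -drf * rmid)  # per-radian vector area
        object.__setattr__(self, "jface_Sr", dxf * rmid + np.zeros_like(r1))
        object.__setattr__(self, "jface_Px", -drf)         # planar (length-weighted normal)
        object.__setattr__(self, "jface_Pr", dxf + np.zeros_like(r1))
        object.__setattr__(self, "jface_xc", 0.5 * (x_faces[:-1] + x_faces[1:])[:, None]
                           + np.zeros_like(r1))
        object.__setattr__(self, "jface_rc", rmid)

    @property
    def nx(self) -> int:
        return self.x_faces.size - 1

    @property
    def nr(self) -> int:
        return self.r_frac_faces.size - 1

    @property
    def n_cells(self) -> int:
        return self.nx * self.nr

    @property
    def wall_x(self) -> np.ndarray:
        """Axial centers of the wall faces (j = nr)."""
        return self.jface_xc[:, -1]

    @property
    def total_volume(self) -> float:
        """Meshed volume of the full revolved tube [m^3]."""
        return float(2.0 * np.pi * self.vol.sum())

    def refined(self, factor: int = 2) -> "AxisymmetricGrid":
        """Regenerate with ``factor``-times the cell counts, same stretching law."""
        return generate_grid(self.geom, factor * self.nx, factor * self.nr, self.clustering)


def generate_grid(
    geom: StenosisGeometry,
    n_axial: int,
    n_radial: int,
    clustering: GridClustering | None = None,
) -> AxisymmetricGrid:
    """Generate the structured nonuniform grid for a stenosis geometry.

    ``n_axial``/``n_radial`` are cell counts; resolutions of at least
    roughly 40 x 10 are needed for meaningful flow solutions, but any
    positive counts >= 2 produce a valid mesh (useful for cheap tests).
    """
    if not (isinstance(n_axial, (int, np.integer)) and n_axial >= 2):
        raise ConfigurationError(f"n_axial must be an integer >= 2, got {n_axial!r}")
    if not (isinstance(n_radial, (int, np.integer)) and n_radial >= 2):
        raise ConfigurationError(f"n_radial must be an integer >= 2, got {n_radial!r}")
    cl = clustering if clustering is not None else GridClustering()
    x_faces = _axial_faces(geom, int(n_axial), cl)
    fr = _radial_fractions(int(n_radial), cl.radial_beta)
    return AxisymmetricGrid(geom=geom, x_faces=x_faces, r_frac_faces=fr, clustering=cl)
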