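"""Tagged structured meshes of the fluid domain.

The 2D longitudinal section of the chamber is rectilinear (a rectangle minus
the solid pedestal), so a boundary-fitted tensor-product grid represents the
geometry exactly: grid faces coincide with the pedestal edges, the cell-disc
plane and the domain walls.  Cells are quadrilaterals; the staggered-grid
solvers in :mod:`zonesim.flow` and :mod:`zonesim.oxygen` operate directly on
the structured arrays, while ``nodes``/``elements``/``boundary_facets``
expose the generic unstructured view of the same mesh.

Vertical grid spacing is geometrically graded towards the cell-surface plane
so the oxygen boundary layer at the monolayer is resolved; the smallest
spacing there is at most ``surface_layer_fraction * surface_layer_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CultureConfig

__all__ = [
    "INLET",
    "OUTLET",
    "WALL",
    "CELL_SURFACE",
    "TAG_NAMES",
    "Mesh",
    "MeshError",
    "build_mesh",
    "build_channel_mesh",
    "build_column_mesh",
    "export_vtk",
]

INLET, OUTLET, WALL, CELL_SURFACE = 1, 2, 3, 4
TAG_NAMES = {INLET: "inlet", OUTLET: "outlet", WALL: "wall", CELL_SURFACE: "cell_surface"}


class MeshError(ValueError):
    """Degenerate or inconsistent mesh geometry."""


@dataclass
class Mesh:
    """Structured tagged mesh of the fluid region.

    ``fluid[j, i]`` flags cell (column i, row j) as fluid; solid cells belong
    to the pedestal.  Boundary tags are stored per side: ``left_tag[j]`` /
    ``right_tag[j]`` for the vertical domain boundary faces, ``top_tag[i]``
    for the lid, and ``bottom_tag[i]`` for the horizontal face closing each
    fluid column from below (the chamber base or the pedestal top).
    """

    xf: np.ndarray  # x face coordinates, (nx+1,)
    zf: np.ndarray  # z face coordinates, (nz+1,)
    fluid: np.ndarray  # (nz, nx) bool
    refinement_level: int
    left_tag: np.ndarray  # (nz,) int
    right_tag: np.ndarray  # (nz,) int
    top_tag: np.ndarray  # (nx,) int
    bottom_tag: np.ndarray  # (nx,) int
    surface_z: float  # z of the cell-monolayer plane
    inlet_u: np.ndarray  # (nz,) prescribed face-average u on the left boundary
    inlet_q2d: float  # per-width volumetric flux through the inlet, m^2/s
    _j_bot: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.xf = np.asarray(self.xf, float)
        self.zf = np.asarray(self.zf, float)
        self.fluid = np.asarray(self.fluid, bool)
        if not self.fluid.any():
            raise MeshError("fluid region has zero measure")
        if np.any(np.diff(self.xf) <= 0) or np.any(np.diff(self.zf) <= 0):
            raise MeshError("face coordinates must be strictly increasing")
        nz, nx = self.fluid.shape
        if self.xf.size != nx + 1 or self.zf.size != nz + 1:
            raise MeshError("face arrays inconsistent with fluid mask shape")
        # first fluid row of each column (columns are solid from the base up)
        jb = np.full(nx, nz, dtype=int)
        for i in range(nx):
            rows = np.nonzero(self.fluid[:, i])[0]
            if rows.size:
                jb[i] = rows[0]
                if not self.fluid[rows[0]:, i].all():
                    raise MeshError("fluid columns must be contiguous in z")
        self._j_bot = jb

    # -- basic measures -----------------------------------------------------

    @property
    def nx(self) -> int:
        return self.fluid.shape[1]

    @property
    def nz(self) -> int:
        return self.fluid.shape[0]

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.xf)

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.zf)

    @property
    def xc(self) -> np.ndarray:
        return 0.5 * (self.xf[1:] + self.xf[:-1])

    @property
    def zc(self) -> np.ndarray:
        return 0.5 * (self.zf[1:] + self.zf[:-1])

    @property
    def n_elements(self) -> int:
        return int(self.fluid.sum())

    def fluid_area(self) -> float:
        """Total fluid area of the section, m^2 (exact for this geometry)."""
        return float((np.outer(self.dz, self.dx) * self.fluid).sum())

    def min_surface_spacing(self) -> float:
        """Smallest vertical spacing of the cell layer above the monolayer."""
        js = self.surface_rows()
        return float(min(self.dz[j] for j in js)) if js else np.inf

    # -- unstructured views ---------------------------------------------------

    @property
    def nodes(self) -> np.ndarray:
        """(N, 2) array of grid node coordinates (x, z)."""
        X, Z = np.meshgrid(self.xf, self.zf)
        return np.column_stack([X.ravel(), Z.ravel()])

    @property
    def elements(self) -> np.ndarray:
        """(M, 4) quad connectivity of fluid cells into ``nodes``."""
        nxp = self.nx + 1
        js, is_ = np.nonzero(self.fluid)
        n00 = js * nxp + is_
        return np.column_stack([n00, n00 + 1, n00 + 1 + nxp, n00 + nxp])

    def boundary_facets(self):
        """All boundary faces of the fluid region as (x0, z0, x1, z1, tag).

        Every facet carries exactly one tag; interior fluid/solid interfaces
        (pedestal sides) are walls unless they lie on the cell-disc plane.
        """
        facets = []
        nz, nx = self.nz, self.nx
        f = self.fluid
        for j in range(nz):
            for i in range(nx + 1):  # vertical faces
                left = f[j, i - 1] if i > 0 else None
                right = f[j, i] if i < nx else None
                if i == 0 and right:
                    tag = self.left_tag[j]
                elif i == nx and left:
                    tag = self.right_tag[j]
                elif i not in (0, nx) and (left != right):
                    tag = WALL
                else:
                    continue
                facets.append((self.xf[i], self.zf[j], self.xf[i], self.zf[j + 1], int(tag)))
        for i in range(nx):
            for j in range(nz + 1):  # horizontal faces
                below = f[j - 1, i] if j > 0 else None
                above = f[j, i] if j < nz else None
                if j == nz and below:
                    tag = self.top_tag[i]
                elif above and (j == 0 or not below):
                    tag = self.bottom_tag[i] if j == self._j_bot[i] else WALL
                elif below and (j < nz and not above):
                    tag = WALL  # solid above fluid (not present in chamber builds)
                else:
                    continue
                facets.append((self.xf[i], self.zf[j], self.xf[i + 1], self.zf[j], int(tag)))
        return facets

    def boundary_measure(self, tag: int | None = None) -> float:
        """Total length of boundary facets carrying ``tag`` (all if None)."""
        total = 0.0
        for x0, z0, x1, z1, t in self.boundary_facets():
            if tag is None or t == tag:
                total += abs(x1 - x0) + abs(z1 - z0)
        return total

    # -- cell-surface access --------------------------------------------------

    def surface_cols(self) -> np.ndarray:
        """Column indices whose bottom face is tagged ``cell_surface``."""
        return np.nonzero(self.bottom_tag == CELL_SURFACE)[0]

    def surface_rows(self) -> list[int]:
        """Row index of the first fluid cell above the surface, per column."""
        return [int(self._j_bot[i]) for i in self.surface_cols()]

    def surface_faces(self):
        """(col, row-above, x-centre, width) for each cell-surface face."""
        cols = self.surface_cols()
        return [
            (int(i), int(self._j_bot[i]), float(self.xc[i]), float(self.dx[i]))
            for i in cols
        ]


# ---------------------------------------------------------------------------
# spacing generators


def _uniform(a: float, b: float, target: float) -> np.ndarray:
    n = max(1, int(round((b - a) / target)))
    return np.linspace(a, b, n + 1)


def _graded(a: float, b: float, dz_min: float, dz_max: float, ratio: float = 1.2) -> np.ndarray:
    """Faces of [a, b] with spacing growing geometrically from ``a``."""
    length = b - a
    spacings = []
    dz, total = dz_min, 0.0
    while total < length:
        spacings.append(dz)
        total += dz
        dz = min(dz * ratio, dz_max)
    s = np.asarray(spacings) * (length / total)
    return a + np.concatenate([[0.0], np.cumsum(s)])


def _parabolic_face_averages(zf: np.ndarray, lo: float, hi: float, q2d: float) -> np.ndarray:
    """Face-averaged velocities of a parabolic profile on [lo, hi].

    The antiderivative is evaluated at face coordinates so the discrete flux
    sum(u_j * dz_j) telescopes to exactly ``q2d``.
    """
    half = 0.5 * (hi - lo)
    zc = 0.5 * (hi + lo)
    umax = 0.75 * q2d / half

    def antider(z):
        s = np.clip((z - zc) / half, -1.0, 1.0)
        return umax * half * (s - s**3 / 3.0 + 2.0 / 3.0)

    flux = antider(zf[1:]) - antider(zf[:-1])
    return flux / np.diff(zf)


# ---------------------------------------------------------------------------
# builders


def build_mesh(config: CultureConfig, refinement_level: int = 2) -> Mesh:
    """Build the tagged chamber mesh at the given refinement level.

    Element counts grow monotonically with ``refinement_level`` and the
    vertical spacing at the cell surface halves with each level.
    """
    if refinement_level < 0:
        raise MeshError("refinement_level must be >= 0")
    g = config.geometry
    num = config.numerics
    W = 2.0 * g.chamber_radius
    H = g.chamber_depth
    h = g.insert_height
    xc_mid = g.chamber_radius
    scale = 2**refinement_level
    dz_target = H / (num.cells_across * scale)
    dx_target = W / (num.cells_across * scale)
    dz_min = num.surface_layer_fraction * num.surface_layer_scale / scale

    # x faces: exact breakpoints at pedestal and coverslip edges
    breaks = sorted(
        {
            0.0,
            xc_mid - g.pedestal_radius,
            xc_mid - g.coverslip_radius,
            xc_mid + g.coverslip_radius,
            xc_mid + g.pedestal_radius,
            W,
        }
    )
    xf = np.concatenate(
        [_uniform(a, b, dx_target)[:-1] for a, b in zip(breaks[:-1], breaks[1:])]
        + [[W]]
    )

    # z faces: graded towards the cell-surface plane z = h
    if h > 0:
        below = _uniform(0.0, h, dz_target)
        above = _graded(h, H, dz_min, dz_target)
        zf = np.concatenate([below[:-1], above])
    else:
        zf = _graded(0.0, H, dz_min, dz_target)

    nz, nx = zf.size - 1, xf.size - 1
    zc = 0.5 * (zf[1:] + zf[:-1])
    xcents = 0.5 * (xf[1:] + xf[:-1])
    fluid = np.ones((nz, nx), dtype=bool)
    if h > 0:
        solid = (np.abs(xcents - xc_mid) < g.pedestal_radius)[None, :] & (zc < h)[:, None]
        fluid &= ~solid
    if not fluid.any():
        raise MeshError("degenerate geometry: no fluid cells")

    port_lo = g.port_center_height - g.port_radius
    port_hi = g.port_center_height + g.port_radius
    in_port = (zc > port_lo) & (zc < port_hi)
    left_tag = np.where(in_port, INLET, WALL)
    right_tag = np.where(in_port, OUTLET, WALL)
    top_tag = np.full(nx, WALL)
    on_disc = np.abs(xcents - xc_mid) < g.coverslip_radius
    bottom_tag = np.where(on_disc, CELL_SURFACE, WALL)

    inlet_u = np.zeros(nz)
    q2d = config.inlet_flux_2d
    if q2d > 0:
        inlet_u = _parabolic_face_averages(zf, port_lo, port_hi, q2d)
        inlet_u[left_tag != INLET] = 0.0
        # faces straddling the port edges are untagged; rescale so the
        # discrete inflow matches the prescribed flux exactly
        carried = float(np.sum(inlet_u * np.diff(zf)))
        if carried <= 0:
            raise MeshError("inlet port is unresolved at this refinement level")
        inlet_u *= q2d / carried

    return Mesh(
        xf=xf,
        zf=zf,
        fluid=fluid,
        refinement_level=refinement_level,
        left_tag=left_tag,
        right_tag=right_tag,
        top_tag=top_tag,
        bottom_tag=bottom_tag,
        surface_z=h,
        inlet_u=inlet_u,
        inlet_q2d=q2d,
    )


def build_channel_mesh(
    length: float,
    gap: float,
    q2d: float,
    refinement_level: int = 2,
    cells_across: int = 24,
) -> Mesh:
    """Parallel-plate channel: parabolic inflow left, outflow right.

    The bottom plate is tagged ``cell_surface`` so the wall-shear extraction
    used for the chamber applies unchanged.  ``q2d`` is the per-width flux
    (m^2/s); the analytic wall shear is ``6 mu q2d / gap^2``.
    """
    scale = 2**refinement_level
    xf = _uniform(0.0, length, length / (cells_across * scale))
    zf = _uniform(0.0, gap, gap / (cells_across * scale))
    nz, nx = zf.size - 1, xf.size - 1
    fluid = np.ones((nz, nx), dtype=bool)
    inlet_u = _parabolic_face_averages(zf, 0.0, gap, q2d)
    return Mesh(
        xf=xf,
        zf=zf,
        fluid=fluid,
        refinement_level=refinement_level,
        left_tag=np.full(nz, INLET),
        right_tag=np.full(nz, OUTLET),
        top_tag=np.full(nx, WALL),
        bottom_tag=np.full(nx, CELL_SURFACE),
        surface_z=0.0,
        inlet_u=inlet_u,
        inlet_q2d=q2d,
    )


def build_column_mesh(
    width: float,
    depth: float,
    refinement_level: int = 2,
    cells_across: int = 24,
) -> Mesh:
    """Stagnant 1D column: top face holds the supply concentration (tagged
    inlet, zero velocity), bottom face is the consuming cell surface."""
    scale = 2**refinement_level
    xf = _uniform(0.0, width, width / 4)
    zf = _uniform(0.0, depth, depth / (cells_across * scale))
    nz, nx = zf.size - 1, xf.size - 1
    return Mesh(
        xf=xf,
        zf=zf,
        fluid=np.ones((nz, nx), dtype=bool),
        refinement_level=refinement_level,
        left_tag=np.full(nz, WALL),
        right_tag=np.full(nz, WALL),
        top_tag=np.full(nx, INLET),
        bottom_tag=np.full(nx, CELL_SURFACE),
        surface_z=0.0,
        inlet_u=np.zeros(nz),
        inlet_q2d=0.0,
    )


def export_vtk(mesh: Mesh, path, cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh (and optional per-cell fields) as legacy ASCII VTK."""
    nodes = mesh.nodes
    elements = mesh.elements
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nzonesim mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        for x, z in nodes:
            fh.write(f"{x:.9e} {z:.9e} 0.0\n")
        fh.write(f"CELLS {len(elements)} {5 * len(elements)}\n")
        for quad in elements:
            fh.write("4 " + " ".join(str(int(n)) for n in quad) + "\n")
        fh.write(f"CELL_TYPES {len(elements)}\n")
        fh.write("9\n" * len(elements))
        if cell_data:
            fh.write(f"CELL_DATA {len(elements)}\n")
            js, is_ = np.nonzero(mesh.fluid)
            for name, arr in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                vals = np.asarray(arr)[js, is_] if np.asarray(arr).ndim == 2 else np.asarray(arr)
                for v in vals:
                    fh.write(f"{v:.9e}\n")
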