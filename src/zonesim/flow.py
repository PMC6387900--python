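"""Steady incompressible flow in the chamber section and wall shear stress.

The discretisation is a staggered (MAC) finite-volume scheme: horizontal
velocity u on vertical faces, vertical velocity w on horizontal faces,
pressure at cell centres.  Continuity is enforced exactly per cell, so mass
is conserved to solver precision and the inf-sup pairing is stable without
pressure stabilisation.  At the chamber's perfusion rates the Reynolds
number is small and the Stokes system (the default) is solved in one sparse
direct factorisation; the convective term can be switched on, in which case
it is Picard-linearised with first-order upwinding and iterated to the
configured relative tolerance.

Boundary conditions: prescribed parabolic inflow on the inlet port,
traction-free (do-nothing) outflow on the outlet port, no-slip on every
wall and on the pedestal/cell surface.  The outlet pins the pressure level;
for all-Dirichlet meshes a zero-mean Lagrange multiplier fixes the gauge,
and the reported pressure is always re-gauged to zero mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import CultureConfig
from .mesh import INLET, OUTLET, Mesh
from .profiles import SurfaceProfile

__all__ = ["FlowField", "FlowSolverError", "solve_flow", "wall_shear", "mean_surface_shear"]


class FlowSolverError(RuntimeError):
    """Solver failure; carries the residual history when iterative."""

    def __init__(self, message: str, residuals: list[float] | None = None):
        super().__init__(message)
        self.residuals = residuals or []


@dataclass
class FlowField:
    """Velocity/pressure solution on a staggered mesh.

    ``u`` has shape (nz, nx+1) (vertical faces), ``w`` (nz+1, nx)
    (horizontal faces), ``p`` (nz, nx) (cell centres, zero in solid cells,
    defined up to the zero-mean gauge).
    """

    mesh: Mesh
    config: CultureConfig
    u: np.ndarray
    w: np.ndarray
    p: np.ndarray
    reynolds_number: float
    converged: bool
    residuals: list[float] = field(default_factory=list)

    def inlet_flux(self) -> float:
        """Volumetric inflow per unit width across inlet faces, m^2/s."""
        dz = self.mesh.dz
        left = self.mesh.left_tag == INLET
        top = self.mesh.top_tag == INLET
        q = float(np.sum(self.u[left, 0] * dz[left]))
        if top.any():  # column meshes: inflow through the top face
            q += float(np.sum(-self.w[-1, top] * self.mesh.dx[top]))
        return q

    def outlet_flux(self) -> float:
        """Volumetric outflow per unit width across outlet faces, m^2/s."""
        dz = self.mesh.dz
        right = self.mesh.right_tag == OUTLET
        return float(np.sum(self.u[right, -1] * dz[right]))

    def divergence(self) -> np.ndarray:
        """Per-cell net volumetric flux (m^2/s); zero for converged flow."""
        m = self.mesh
        div = (self.u[:, 1:] - self.u[:, :-1]) * m.dz[:, None] + (
            self.w[1:, :] - self.w[:-1, :]
        ) * m.dx[None, :]
        return np.where(m.fluid, div, 0.0)

    def max_divergence_rel(self) -> float:
        """Largest cell imbalance relative to the inlet flux."""
        q = abs(self.inlet_flux())
        scale = q if q > 0 else 1.0
        return float(np.abs(self.divergence()).max() / scale)

    def speed(self) -> np.ndarray:
        """Cell-centred speed magnitude (nz, nx)."""
        uc = 0.5 * (self.u[:, 1:] + self.u[:, :-1])
        wc = 0.5 * (self.w[1:, :] + self.w[:-1, :])
        return np.hypot(uc, wc) * self.mesh.fluid


def _face_maps(mesh: Mesh):
    """Classify staggered faces into unknowns and Dirichlet values."""
    nz, nx = mesh.nz, mesh.nx
    f = mesh.fluid
    u_idx = -np.ones((nz, nx + 1), dtype=int)
    u_val = np.zeros((nz, nx + 1))
    u_outflow = np.zeros((nz, nx + 1), dtype=bool)
    k = 0
    for j in range(nz):
        for i in range(nx + 1):
            if 0 < i < nx and f[j, i - 1] and f[j, i]:
                u_idx[j, i] = k
                k += 1
            elif i == nx and f[j, nx - 1] and mesh.right_tag[j] == OUTLET:
                u_idx[j, i] = k
                u_outflow[j, i] = True
                k += 1
            elif i == 0 and f[j, 0] and mesh.left_tag[j] == INLET:
                u_val[j, i] = mesh.inlet_u[j]
    n_u = k
    w_idx = -np.ones((nz + 1, nx), dtype=int)
    for j in range(1, nz):
        for i in range(nx):
            if f[j - 1, i] and f[j, i]:
                w_idx[j, i] = k
                k += 1
    n_w = k - n_u
    p_idx = -np.ones((nz, nx), dtype=int)
    cells = np.argwhere(f)
    for j, i in cells:
        p_idx[j, i] = k
        k += 1
    return u_idx, u_val, u_outflow, w_idx, p_idx, n_u, n_w, k


def _assemble(mesh: Mesh, config: CultureConfig, maps, u_old=None, w_old=None):
    """Assemble the saddle-point system (momentum, continuity, gauge)."""
    u_idx, u_val, u_outflow, w_idx, p_idx, n_u, n_w, n_base = maps
    nz, nx = mesh.nz, mesh.nx
    f = mesh.fluid
    dx, dz = mesh.dx, mesh.dz
    xc, zc = mesh.xc, mesh.zc
    xf = mesh.xf
    mu = config.fluid.dynamic_viscosity
    rho = config.fluid.density
    inertia = u_old is not None

    # the traction-free outlet pins the pressure level; a zero-mean gauge
    # multiplier is only needed for all-Dirichlet meshes (e.g. stagnant columns)
    has_outlet = bool(u_outflow.any())
    n_tot = n_base if has_outlet else n_base + 1
    rows, cols, vals = [], [], []
    rhs = np.zeros(n_tot)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    def u_face(j, i):
        """(index or -1, value) of the u-face (j, i); None if wall-ghost."""
        if 0 <= j < nz and 0 <= i <= nx:
            near_fluid = (i > 0 and f[j, i - 1]) or (i < nx and f[j, i])
            if near_fluid:
                return u_idx[j, i], u_val[j, i]
        return None

    def w_face(j, i):
        if 0 <= j <= nz and 0 <= i < nx:
            near_fluid = (j > 0 and f[j - 1, i]) or (j < nz and f[j, i])
            if near_fluid:
                return w_idx[j, i], 0.0
        return None

    def couple(row, entry, a):
        """Add -a * (neighbour face) to ``row``; Dirichlet goes to the RHS."""
        idx, val = entry
        if idx >= 0:
            add(row, idx, -a)
        else:
            rhs[row] += a * val

    # -- u momentum ---------------------------------------------------------
    # Interior faces get full control volumes; outflow faces (i == nx) get a
    # half control volume truncated at the boundary with zero traction
    # (-p + mu du/dx = 0) imposed on its outer side.
    for j in range(nz):
        for i in range(1, nx + 1):
            row = u_idx[j, i]
            if row < 0:
                continue
            outflow = u_outflow[j, i]
            dzj = dz[j]
            dxu = (xf[i] - xc[i - 1]) if outflow else (xc[i] - xc[i - 1])
            diag = 0.0

            if not outflow:
                a = mu * dzj / dx[i]
                couple(row, u_face(j, i + 1), a)
                diag += a
            a = mu * dzj / dx[i - 1]
            couple(row, u_face(j, i - 1), a)
            diag += a
            # vertical neighbours; wall-ghost at half spacing when the row
            # above/below is solid or outside the domain
            up = u_face(j + 1, i)
            if up is not None:
                a = mu * dxu / (zc[j + 1] - zc[j])
                couple(row, up, a)
            else:
                a = mu * dxu / (0.5 * dzj)
                # no-slip wall at zf[j+1]
            diag += a
            dn = u_face(j - 1, i)
            if dn is not None:
                a = mu * dxu / (zc[j] - zc[j - 1])
                couple(row, dn, a)
            else:
                a = mu * dxu / (0.5 * dzj)
            diag += a

            if inertia:
                iw = min(i, nx - 1)  # w column index clamped at the boundary
                fe = rho * (u_old[j, i] if outflow else 0.5 * (u_old[j, i] + u_old[j, i + 1])) * dzj
                fw = rho * 0.5 * (u_old[j, i - 1] + u_old[j, i]) * dzj
                fn = rho * 0.5 * (w_old[j + 1, i - 1] + w_old[j + 1, iw]) * dxu
                fs = rho * 0.5 * (w_old[j, i - 1] + w_old[j, iw]) * dxu
                for F, entry in (
                    (fe, None if outflow else u_face(j, i + 1)),
                    (-fw, u_face(j, i - 1)),
                    (fn, u_face(j + 1, i)),
                    (-fs, u_face(j - 1, i)),
                ):
                    diag += max(F, 0.0)
                    if entry is not None:
                        couple(row, entry, max(-F, 0.0))

            add(row, row, diag)
            # pressure gradient (boundary pressure is zero at the outlet)
            if not outflow:
                add(row, p_idx[j, i], dzj)
            add(row, p_idx[j, i - 1], -dzj)

    # -- w momentum ---------------------------------------------------------
    for j in range(1, nz):
        for i in range(nx):
            row = w_idx[j, i]
            if row < 0:
                continue
            dxi = dx[i]
            dzw = zc[j] - zc[j - 1]
            diag = 0.0

            for (jn, in_), a in (((j + 1, i), mu * dxi / dz[j]), ((j - 1, i), mu * dxi / dz[j - 1])):
                couple(row, w_face(jn, in_), a)
                diag += a
            for in_ in (i + 1, i - 1):
                if 0 <= in_ < nx:
                    if f[j - 1, in_] or f[j, in_]:
                        a = mu * dzw / abs(xc[in_] - xc[i])
                        couple(row, w_face(j, in_), a)
                        diag += a
                    else:
                        # neighbour position is solid: no-slip wall at the
                        # shared face, half a cell width away
                        diag += mu * dzw / (0.5 * dxi)
                else:
                    # domain boundary: outflow -> zero x-gradient, else wall
                    at_out = in_ >= nx and (
                        mesh.right_tag[j] == OUTLET or mesh.right_tag[j - 1] == OUTLET
                    )
                    if not at_out:
                        diag += mu * dzw / (0.5 * dxi)
            if inertia:
                fe = rho * 0.5 * (u_old[j - 1, i + 1] + u_old[j, i + 1]) * dzw
                fw = rho * 0.5 * (u_old[j - 1, i] + u_old[j, i]) * dzw
                fn = rho * 0.5 * (w_old[j, i] + w_old[j + 1, i]) * dxi
                fs = rho * 0.5 * (w_old[j - 1, i] + w_old[j, i]) * dxi
                for F, entry in (
                    (fe, w_face(j, i + 1) if i + 1 < nx else None),
                    (-fw, w_face(j, i - 1) if i - 1 >= 0 else None),
                    (fn, w_face(j + 1, i)),
                    (-fs, w_face(j - 1, i)),
                ):
                    diag += max(F, 0.0)
                    if entry is not None:
                        couple(row, entry, max(-F, 0.0))

            add(row, row, diag)
            add(row, p_idx[j, i], dxi)
            add(row, p_idx[j - 1, i], -dxi)

    # -- continuity + gauge -------------------------------------------------
    gauge = n_tot - 1
    for j in range(nz):
        for i in range(nx):
            row = p_idx[j, i]
            if row < 0:
                continue
            area = dx[i] * dz[j]
            for entry, coeff in (
                (u_face(j, i + 1), dz[j]),
                (u_face(j, i), -dz[j]),
                (w_face(j + 1, i), dx[i]),
                (w_face(j, i), -dx[i]),
            ):
                idx, val = entry
                if idx >= 0:
                    add(row, idx, coeff)
                else:
                    rhs[row] -= coeff * val
            if not has_outlet:
                add(row, gauge, area)
                add(gauge, row, area)

    A = sp.csr_matrix((vals, (rows, cols)), shape=(n_tot, n_tot))
    return A, rhs


def solve_flow(config: CultureConfig, mesh: Mesh) -> FlowField:
    """Solve steady incompressible flow at the configured perfusion rate.

    Returns a converged :class:`FlowField`; raises :class:`FlowSolverError`
    if the Picard iteration (inertia enabled) fails to converge.
    """
    num = config.numerics
    mu = config.fluid.dynamic_viscosity
    re = (
        config.fluid.density
        * config.inlet_velocity
        * 2.0
        * config.geometry.port_radius
        / mu
    )
    if re > num.re_warning_threshold:
        warnings.warn(
            f"inlet Reynolds number {re:.1f} exceeds the laminar-assumption "
            f"threshold {num.re_warning_threshold}",
            RuntimeWarning,
        )

    maps = _face_maps(mesh)
    u_idx, u_val, u_outflow, w_idx, p_idx, n_u, n_w, n_base = maps

    def unpack(x):
        u = u_val.copy()
        sel = u_idx >= 0
        u[sel] = x[u_idx[sel]]
        w = np.zeros((mesh.nz + 1, mesh.nx))
        selw = w_idx >= 0
        w[selw] = x[w_idx[selw]]
        p = np.zeros((mesh.nz, mesh.nx))
        selp = p_idx >= 0
        p[selp] = x[p_idx[selp]]
        p[selp] -= p[selp].mean()  # zero-mean pressure gauge
        return u, w, p

    residuals: list[float] = []
    A, rhs = _assemble(mesh, config, maps)
    x = spla.spsolve(A.tocsc(), rhs)
    u, w, p = unpack(x)

    if num.inertia and config.flow_rate > 0:
        uscale = max(np.abs(u).max(), 1e-300)
        converged = False
        for _ in range(num.max_iterations):
            A, rhs = _assemble(mesh, config, maps, u_old=u, w_old=w)
            x = spla.spsolve(A.tocsc(), rhs)
            u_new, w_new, p = unpack(x)
            change = max(np.abs(u_new - u).max(), np.abs(w_new - w).max()) / uscale
            residuals.append(change)
            u, w = u_new, w_new
            if change <= num.nonlinear_tol:
                converged = True
                break
        if not converged:
            raise FlowSolverError(
                f"Picard iteration did not reach {num.nonlinear_tol} in "
                f"{num.max_iterations} iterations",
                residuals,
            )
    else:
        lin_res = float(np.linalg.norm(A @ x - rhs) / max(np.linalg.norm(rhs), 1e-300))
        residuals.append(lin_res)

    field = FlowField(
        mesh=mesh,
        config=config,
        u=u,
        w=w,
        p=p,
        reynolds_number=re,
        converged=True,
        residuals=residuals,
    )
    return field


def wall_shear(flow: FlowField, config: CultureConfig) -> SurfaceProfile:
    """Shear-stress magnitude along the cell-disc centreline.

    The tangential viscous traction mu * du/dz at the surface is extracted
    with a one-sided quadratic fit through the no-slip surface value and the
    two cell-centre velocities above it (exact for locally parabolic flow).
    """
    if not flow.converged:
        raise FlowSolverError("flow field is not converged")
    m = flow.mesh
    mu = config.fluid.dynamic_viscosity
    zs = m.surface_z
    positions, values, widths = [], [], []
    for i, j, xcent, width in m.surface_faces():
        u1 = 0.5 * (flow.u[j, i] + flow.u[j, i + 1])
        z1 = m.zc[j] - zs
        if j + 1 < m.nz and m.fluid[j + 1, i]:
            u2 = 0.5 * (flow.u[j + 1, i] + flow.u[j + 1, i + 1])
            z2 = m.zc[j + 1] - zs
            dudz = (u1 * z2**2 - u2 * z1**2) / (z1 * z2 * (z2 - z1))
        else:
            dudz = u1 / z1
        positions.append(xcent)
        values.append(abs(mu * dudz))
        widths.append(width)
    return SurfaceProfile(
        positions=np.asarray(positions),
        values=np.asarray(values),
        quantity="shear",
        units="Pa",
        weights=np.asarray(widths),
    )


def mean_surface_shear(profile: SurfaceProfile) -> float:
    """Length-weighted mean shear magnitude over the disc centreline, Pa."""
    if profile.quantity != "shear":
        raise ValueError(f"expected a shear profile, got {profile.quantity!r}")
    return profile.mean()
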