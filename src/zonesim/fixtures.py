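"""Analytic benchmark cases, synthetic data and parameter recovery.

Everything the verification suite needs is generated here, with no external
data: a plane-Poiseuille channel (closed-form wall shear) exercises the flow
solver, a stagnant diffusion column with Michaelis-Menten uptake at its base
(closed-form quadratic for the surface concentration, cross-checked by an
independent dense finite-difference solve) exercises the transport solver,
and noisy synthetic surface profiles close the loop on the uptake kinetics
through least-squares recovery of sigma*Vmax.

The closed forms here share no discretisation with the PDE solvers, so
agreement between the two routes is evidence of correctness rather than a
tautology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.linalg import solve_banded

from .config import CultureConfig, OxygenKinetics, build_geometry
from .flow import mean_surface_shear, solve_flow, wall_shear
from .mesh import Mesh, build_channel_mesh, build_column_mesh, build_mesh
from .oxygen import oxygen_mass_balance, solve_oxygen, surface_oxygen_profile
from .profiles import SurfaceProfile

__all__ = [
    "AnalyticCase",
    "poiseuille_case",
    "stagnant_mm_case",
    "finite_difference_surface_conc",
    "synthetic_profile",
    "recover_vmax",
    "VmaxEstimate",
    "verify_all",
]


@dataclass
class AnalyticCase:
    """A solvable configuration paired with its closed-form solution.

    ``analytic`` maps scalar names (e.g. ``wall_shear``, ``surface_conc``)
    to exact values; ``mesh_builder(level)`` yields the mesh the solvers
    should be run on; ``tolerance`` is the contracted relative agreement
    between solver and closed form at refinement level 2.
    """

    label: str
    config: CultureConfig
    mesh_builder: Callable[[int], Mesh]
    analytic: dict[str, float]
    tolerance: float
    _self_check: Callable[[], float] = field(default=lambda: 0.0, repr=False)

    def mesh(self, refinement_level: int = 2) -> Mesh:
        return self.mesh_builder(refinement_level)

    def self_check(self, tol: float = 1e-9) -> None:
        """Verify the closed form's internal consistency (flux balances)."""
        err = self._self_check()
        if not (err <= tol):
            raise AssertionError(
                f"{self.label}: closed form inconsistent (residual {err:.3e})"
            )


def poiseuille_case(
    flow_rate: float,
    gap: float,
    width: float,
    viscosity: float = 0.7e-3,
) -> AnalyticCase:
    """Plane Poiseuille flow between parallel plates.

    A channel of gap ``gap`` carries the volumetric rate ``flow_rate``
    through a width ``width``; the exact wall shear is ``6 mu Q / (w gap^2)``
    and the centreline velocity ``1.5 q / gap`` with ``q = Q / w``.
    """
    for name, v in (("flow_rate", flow_rate), ("gap", gap), ("width", width), ("viscosity", viscosity)):
        if not (v > 0):
            raise ValueError(f"{name} must be positive")
    q2d = flow_rate / width
    shear = 6.0 * viscosity * flow_rate / (width * gap**2)
    u_max = 1.5 * q2d / gap

    def check() -> float:
        # the parabolic profile u(z) = 6 q z (gap - z) / gap^3 must carry
        # exactly q and exert mu u'(0) = shear at the wall
        z = np.linspace(0.0, gap, 20001)
        u = 6.0 * q2d * z * (gap - z) / gap**3
        flux_err = abs(simpson(u, x=z) - q2d) / q2d  # Simpson: exact for parabolas
        shear_err = abs(viscosity * 6.0 * q2d / gap**2 - shear) / shear
        return max(flux_err, shear_err)

    config = build_geometry(
        flow_rate=flow_rate,
        dynamic_viscosity=viscosity,
    )
    return AnalyticCase(
        label="poiseuille",
        config=config,
        mesh_builder=lambda level: build_channel_mesh(
            length=2.0 * gap, gap=gap, q2d=q2d, refinement_level=level
        ),
        analytic={"wall_shear": shear, "u_max": u_max, "q2d": q2d},
        tolerance=0.02,
        _self_check=check,
    )


def stagnant_mm_case(
    c0: float,
    depth: float,
    diffusivity: float,
    sigma_vmax: float,
    km: float,
) -> AnalyticCase:
    """Stagnant 1D column with Michaelis-Menten uptake at its base.

    At steady state the linear diffusion profile and the uptake law share
    one flux J, which eliminates to a quadratic for the surface value:

        c_s^2 + (km + sigma_vmax * L / D - c0) * c_s - km * c0 = 0

    whose positive root is the exact surface concentration.
    """
    for name, v in (("c0", c0), ("depth", depth), ("diffusivity", diffusivity), ("km", km)):
        if not (v > 0):
            raise ValueError(f"{name} must be positive")
    if sigma_vmax < 0:
        raise ValueError("sigma_vmax must be >= 0")
    b = km + sigma_vmax * depth / diffusivity - c0
    disc = b * b + 4.0 * km * c0
    # numerically stable positive root (avoids cancellation for large b)
    c_s = 2.0 * km * c0 / (b + math.sqrt(disc)) if b > 0 else 0.5 * (-b + math.sqrt(disc))
    if not (c_s > 0):
        raise ValueError("no positive root: closed form internally inconsistent")
    flux = sigma_vmax * c_s / (km + c_s)

    def check() -> float:
        j_mm = sigma_vmax * c_s / (km + c_s)
        j_diff = diffusivity * (c0 - c_s) / depth
        # normalise by the natural flux scales of the problem
        scale = max(sigma_vmax, diffusivity * c0 / depth)
        return abs(j_mm - j_diff) / scale

    kin = OxygenKinetics()  # defaults give the reference areal density
    density = kin.areal_density(6.5e-3)
    config = build_geometry(
        flow_rate=0.0,
        inlet_oxygen=c0,
        oxygen_diffusivity=diffusivity,
        vmax_per_cell=sigma_vmax / density,
        km=km,
    )
    return AnalyticCase(
        label="stagnant_mm",
        config=config,
        mesh_builder=lambda level: build_column_mesh(
            width=1e-3, depth=depth, refinement_level=level
        ),
        analytic={"surface_conc": c_s, "uptake_flux": flux},
        tolerance=0.01,
        _self_check=check,
    )


def finite_difference_surface_conc(
    c0: float,
    depth: float,
    diffusivity: float,
    sigma_vmax: float,
    km: float,
    n_nodes: int = 10_000,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> float:
    """Brute-force 1D finite-difference solve of the stagnant column.

    Dense node-based discretisation of D c'' = 0 with c(L) = c0 and the
    Michaelis-Menten flux at z = 0, Picard-iterated on the uptake
    denominator.  Independent of both the closed form and the 2D solver.
    """
    dz = depth / (n_nodes - 1)
    c = np.full(n_nodes, c0)
    for _ in range(max_iter):
        k_up = sigma_vmax / (km + c[0])
        # tridiagonal system: interior Laplacian, Robin at node 0, Dirichlet top
        ab = np.zeros((3, n_nodes))
        rhs = np.zeros(n_nodes)
        ab[1, 1:-1] = -2.0
        ab[0, 2:] = 1.0
        ab[2, :-2] = 1.0
        # node 0: D (c1 - c0_node)/dz = k_up * c0_node
        ab[1, 0] = -(diffusivity / dz + k_up)
        ab[0, 1] = diffusivity / dz
        ab[1, -1] = 1.0  # Dirichlet top node (its subdiagonal entry is zero)
        ab[2, -2] = 0.0
        rhs[-1] = c0
        c_new = solve_banded((1, 1), ab, rhs)
        if abs(c_new[0] - c[0]) <= tol * max(c0, 1e-300):
            return float(c_new[0])
        c = c_new
    raise RuntimeError("finite-difference Picard iteration did not converge")


def synthetic_profile(
    case: AnalyticCase,
    noise_sd: float,
    n_points: int,
    seed: int,
    disc_radius: float = 6.5e-3,
) -> SurfaceProfile:
    """Noisy synthetic surface-oxygen profile drawn from an analytic case.

    Samples the case's exact surface concentration at ``n_points`` positions
    across the disc with additive zero-mean Gaussian noise of standard
    deviation ``noise_sd`` (mol/m^3).  Reproducible under a fixed ``seed``
    (explicitly required; there is no global random state).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if "surface_conc" not in case.analytic:
        raise ValueError(f"case {case.label!r} has no surface concentration")
    rng = np.random.default_rng(seed)
    positions = np.linspace(-disc_radius, disc_radius, n_points)
    values = case.analytic["surface_conc"] + rng.normal(0.0, noise_sd, n_points)
    return SurfaceProfile(
        positions=positions, values=values, quantity="oxygen", units="mol/m^3"
    )


@dataclass
class VmaxEstimate:
    """Least-squares estimate of the areal uptake capacity sigma*Vmax."""

    estimate: float  # mol/(m^2 s)
    stderr: float
    surface_conc: float  # fitted mean surface concentration, mol/m^3

    def significant(self, z: float = 2.0) -> bool:
        return abs(self.estimate) > z * self.stderr


def recover_vmax(
    profile: SurfaceProfile,
    c0: float,
    depth: float,
    diffusivity: float,
    km: float,
) -> VmaxEstimate:
    """Recover sigma*Vmax from a noisy stagnant-column surface profile.

    Under the stagnant model the surface concentration is spatially uniform,
    so the least-squares fit reduces to matching the closed form to the
    profile mean and inverting the flux balance:

        J = D (c0 - c_bar) / L,   sigma*Vmax = J (km + c_bar) / c_bar.

    The standard error follows by the delta method from the standard error
    of the profile mean.
    """
    if len(profile) < 3:
        raise ValueError("profile too short to estimate a mean and spread")
    c_bar = profile.mean()
    if c_bar <= 0:
        raise ValueError(
            "non-identifiable profile: mean surface concentration is not positive"
        )
    L, D = depth, diffusivity
    estimate = D * (c0 - c_bar) / L * (km + c_bar) / c_bar
    n = len(profile)
    sd = float(np.std(profile.values, ddof=1))
    se_mean = sd / math.sqrt(n)
    dsdc = (D / L) * (-c0 * km / c_bar**2 - 1.0)
    return VmaxEstimate(
        estimate=float(estimate),
        stderr=float(abs(dsdc) * se_mean),
        surface_conc=float(c_bar),
    )


# ---------------------------------------------------------------------------
# end-to-end oracle comparisons


def verify_all(refinement_level: int = 2) -> pd.DataFrame:
    """Run every solver-vs-oracle comparison and return a pass/fail table."""
    rows = []

    def record(name, computed, expected, tol, relative=True):
        scale = abs(expected) if (relative and expected != 0) else 1.0
        err = abs(computed - expected) / scale
        rows.append(
            {
                "check": name,
                "computed": computed,
                "expected": expected,
                "rel_error": err,
                "tolerance": tol,
                "passed": bool(err <= tol),
            }
        )

    # flow solver vs plane Poiseuille
    pcase = poiseuille_case(flow_rate=2.5e-9, gap=1e-3, width=2e-2)
    pcase.self_check()
    mesh = pcase.mesh(refinement_level)
    flow = solve_flow(pcase.config, mesh)
    shear = mean_surface_shear(wall_shear(flow, pcase.config))
    record("poiseuille_wall_shear", shear, pcase.analytic["wall_shear"], pcase.tolerance)
    record("poiseuille_mass_conservation", flow.outlet_flux(), flow.inlet_flux(), 1e-6)

    # transport solver vs stagnant Michaelis-Menten column
    scase = stagnant_mm_case(
        c0=0.21, depth=5e-3, diffusivity=3e-9, sigma_vmax=3e-8, km=5e-3
    )
    scase.self_check()
    mesh = scase.mesh(refinement_level)
    flow0 = solve_flow(scase.config, mesh)
    conc = solve_oxygen(scase.config, mesh, flow0)
    c_s = surface_oxygen_profile(conc, scase.config).mean()
    record("stagnant_mm_surface_conc", c_s, scase.analytic["surface_conc"], scase.tolerance)

    # closed form vs brute-force finite differences
    fd = finite_difference_surface_conc(0.21, 5e-3, 3e-9, 3e-8, 5e-3)
    record("quadratic_vs_brute_force", fd, scase.analytic["surface_conc"], 1e-6)

    # chamber solve mass balance
    cfg = build_geometry()
    mesh = build_mesh(cfg, min(refinement_level, 2))
    flow = solve_flow(cfg, mesh)
    conc = solve_oxygen(cfg, mesh, flow)
    record("chamber_oxygen_mass_balance", oxygen_mass_balance(conc, flow, cfg), 0.0, 1e-2, relative=False)

    return pd.DataFrame(rows)
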