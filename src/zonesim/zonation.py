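"""Zonation design: height sweep, zone selection and the design report.

Liver lobules expose hepatocytes to an oxygen gradient from the periportal
(high O2) to the perivenous (low O2) end of the sinusoid.  The design
procedure implemented here reproduces that gradient across three perfusion
chambers by raising the cell-bearing coverslip on pedestals: cells at the
chamber base see the lowest oxygen (perivenous), and the pedestal height is
increased in 1 mm steps until the mean cell-surface oxygen reaches the
periportal target (default 15 % O2); an intermediate height represents the
central zone.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import CultureConfig, build_geometry
from .flow import mean_surface_shear, solve_flow, wall_shear
from .mesh import build_mesh
from .oxygen import conc_to_percent, solve_oxygen, surface_oxygen_profile, surface_stats

__all__ = [
    "ZoneSummary",
    "SweepResult",
    "SweepWarning",
    "run_configuration",
    "height_sweep",
    "select_zones",
    "table1_report",
]

#: physiological cell-surface oxygen window spanned by the in vivo zones
PHYSIOLOGICAL_O2_PCT = (4.0, 15.0)

ZONE_ORDER = ("periportal", "central", "perivenous")


class SweepWarning(UserWarning):
    """Height sweep diagnostics (unreachable target, non-monotone means)."""


@dataclass
class ZoneSummary:
    """Per-configuration report: the machine twin of one design-table row."""

    insert_height: float  # m
    mean_surface_oxygen: float  # mol/m^3
    mean_surface_oxygen_pct: float  # % O2
    min_surface_oxygen: float  # mol/m^3
    min_surface_oxygen_pct: float  # % O2
    mean_surface_shear: float  # Pa
    zone: str = "unassigned"

    def __post_init__(self) -> None:
        assert self.min_surface_oxygen <= self.mean_surface_oxygen + 1e-15

    def in_physiological_window(self, margin_pct: float = 2.0) -> bool:
        lo, hi = PHYSIOLOGICAL_O2_PCT
        return lo - margin_pct <= self.mean_surface_oxygen_pct <= hi + margin_pct


@dataclass
class SweepResult:
    """All evaluated heights of a sweep plus the stopping height (if any)."""

    summaries: list[ZoneSummary]
    target_pct: float
    stop_height: float | None

    @property
    def heights(self) -> list[float]:
        return [s.insert_height for s in self.summaries]

    @property
    def means_pct(self) -> list[float]:
        return [s.mean_surface_oxygen_pct for s in self.summaries]

    def summary_at(self, height: float, tol: float = 1e-9) -> ZoneSummary:
        for s in self.summaries:
            if abs(s.insert_height - height) <= tol:
                return s
        raise KeyError(f"no sweep entry at height {height} m")


def run_configuration(config: CultureConfig, refinement_level: int = 2) -> ZoneSummary:
    """Run the full pipeline for one configuration.

    build mesh -> solve flow -> wall shear -> solve oxygen -> surface stats.
    """
    try:
        mesh = build_mesh(config, refinement_level)
        flow = solve_flow(config, mesh)
        shear = wall_shear(flow, config)
        conc = solve_oxygen(config, mesh, flow)
        profile = surface_oxygen_profile(conc, config)
    except Exception as exc:
        raise type(exc)(
            f"{exc} (insert_height={config.geometry.insert_height}, "
            f"refinement_level={refinement_level})"
        ) from exc
    mean_c, min_c = surface_stats(profile)
    return ZoneSummary(
        insert_height=config.geometry.insert_height,
        mean_surface_oxygen=mean_c,
        mean_surface_oxygen_pct=conc_to_percent(mean_c),
        min_surface_oxygen=min_c,
        min_surface_oxygen_pct=conc_to_percent(min_c),
        mean_surface_shear=mean_surface_shear(shear),
    )


def _with_height(config: CultureConfig, height: float) -> CultureConfig:
    geometry = replace(config.geometry, insert_height=height)
    return replace(config, geometry=geometry)


def height_sweep(
    base_config: CultureConfig | None = None,
    target_pct: float = 15.0,
    step: float = 1e-3,
    refinement_level: int = 2,
) -> SweepResult:
    """Raise the cells in ``step`` increments until the mean cell-surface
    oxygen reaches ``target_pct`` % O2.

    Evaluates heights 0, step, 2*step, ... and stops at the first height
    whose mean reaches the target, or at the geometric clearance limit (a
    warning is emitted if the target is unreachable).  All evaluated
    summaries are returned.
    """
    if base_config is None:
        base_config = build_geometry()
    if not (target_pct > 0):
        raise ValueError("target_pct must be positive")
    if not (step > 0):
        raise ValueError("step must be positive")
    g = base_config.geometry
    h_max = g.chamber_depth - g.clearance_min
    summaries: list[ZoneSummary] = []
    stop_height = None
    k = 0
    while k * step <= h_max * (1 + 1e-12):
        height = k * step
        summary = run_configuration(_with_height(base_config, height), refinement_level)
        summaries.append(summary)
        if summary.mean_surface_oxygen_pct >= target_pct:
            stop_height = height
            break
        k += 1
    if stop_height is None:
        warnings.warn(
            f"target {target_pct}% O2 not reached within the chamber "
            f"(max mean {max(s.mean_surface_oxygen_pct for s in summaries):.2f}% "
            f"at the clearance limit)",
            SweepWarning,
        )
    means = [s.mean_surface_oxygen_pct for s in summaries]
    if np.any(np.diff(means) < -1e-9):  # tolerance: round-off on flat sweeps
        warnings.warn(
            f"mean surface oxygen is not monotone in height: {means}",
            SweepWarning,
        )
    return SweepResult(summaries=summaries, target_pct=target_pct, stop_height=stop_height)


def select_zones(sweep: SweepResult, central_height: float = 4e-3) -> dict[str, ZoneSummary]:
    """Label the three zone configurations from a completed sweep.

    Height 0 is the perivenous zone, ``central_height`` the central zone and
    the sweep's stopping height the periportal zone.
    """
    if sweep.stop_height is None:
        raise ValueError("sweep did not reach its target; no periportal height")
    if abs(central_height - sweep.stop_height) <= 1e-12 or central_height <= 0:
        raise ValueError("zones must be three distinct heights")
    zones: dict[str, ZoneSummary] = {}
    for label, height in (
        ("perivenous", 0.0),
        ("central", central_height),
        ("periportal", sweep.stop_height),
    ):
        try:
            summary = sweep.summary_at(height)
        except KeyError as exc:
            raise ValueError(f"sweep lacks the {label} height {height} m") from exc
        zones[label] = dataclasses.replace(summary, zone=label)
    return zones


def table1_report(zones: dict[str, ZoneSummary]) -> pd.DataFrame:
    """Design report: one row per zone, ordered periportal/central/perivenous."""
    if set(zones) != set(ZONE_ORDER):
        raise ValueError(f"expected zones {ZONE_ORDER}, got {sorted(zones)}")
    rows = []
    for label in ZONE_ORDER:
        s = zones[label]
        rows.append(
            {
                "zone": label,
                "insert_height_mm": s.insert_height * 1e3,
                "mean_O2_mol_m3": s.mean_surface_oxygen,
                "mean_O2_pct": conc_to_percent(s.mean_surface_oxygen),
                "min_O2_pct": s.min_surface_oxygen_pct,
                "mean_shear_Pa": s.mean_surface_shear,
            }
        )
    return pd.DataFrame(rows)


def report_to_json(report: pd.DataFrame, path) -> None:
    """Serialise a design report losslessly (full float precision)."""
    with open(path, "w") as fh:
        json.dump(report.to_dict(orient="records"), fh, indent=2)


def report_from_json(path) -> pd.DataFrame:
    with open(path) as fh:
        return pd.DataFrame(json.load(fh))
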