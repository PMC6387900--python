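"""Chamber geometry, fluid, kinetics and numerics configuration.

All lengths are SI metres with z = 0 at the chamber base, increasing upward.
The configuration file format (YAML) accepts lengths with an explicit unit
suffix (``"4 mm"``) and flow rates in ``ul/min``; everything is converted to
SI on load.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "ConfigurationError",
    "ConfigWarning",
    "ChamberGeometry",
    "FluidProperties",
    "OxygenKinetics",
    "NumericalSettings",
    "CultureConfig",
    "build_geometry",
    "load_config",
    "save_config",
]

#: Reference concentration for the percent-O2 convention: 1 mol/m^3 == 100 %.
C_REF = 1.0


class ConfigurationError(ValueError):
    """Invalid configuration; the message names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class ConfigWarning(UserWarning):
    """Non-fatal configuration issue (e.g. unknown config-file key)."""


_LENGTH_UNITS = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6}
_FLOW_UNITS = {
    "m3/s": 1.0,
    "ml/min": 1e-6 / 60.0,
    "ul/min": 1e-9 / 60.0,
    "µl/min": 1e-9 / 60.0,
}


def _parse_quantity(value: Any, units: dict[str, float], name: str) -> float:
    """Convert a number (already SI) or a ``"<value> <unit>"`` string to SI."""
    if isinstance(value, bool):
        raise ConfigurationError(name, f"expected a number, got {value!r}")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        s = value.strip()
        for suffix in sorted(units, key=len, reverse=True):
            if s.endswith(suffix):
                num = s[: -len(suffix)].strip()
                try:
                    return float(num) * units[suffix]
                except ValueError:
                    raise ConfigurationError(name, f"cannot parse number in {value!r}")
        raise ConfigurationError(
            name, f"unknown unit in {value!r}; accepted: {sorted(units)}"
        )
    raise ConfigurationError(name, f"expected number or unit string, got {type(value).__name__}")


def parse_length(value: Any, name: str = "length") -> float:
    return _parse_quantity(value, _LENGTH_UNITS, name)


def parse_flow_rate(value: Any, name: str = "flow_rate") -> float:
    return _parse_quantity(value, _FLOW_UNITS, name)


@dataclass
class ChamberGeometry:
    """Parametric 2D longitudinal section of the perfusion chamber.

    The section passes through the inlet and outlet ports.  A solid
    impermeable pedestal of height ``insert_height`` raises the cell-bearing
    coverslip above the base; only the pedestal top disc carries cells.

    The chamber depth and the port centre height are not printed for the
    commercial chamber; the defaults here are the calibrated values used to
    anchor the simulator's design outputs (see the methods note) and every
    field is config-exposed.
    """

    chamber_radius: float = 10e-3
    chamber_depth: float = 24.6e-3
    port_radius: float = 1e-3
    port_center_height: float = 22.9e-3
    insert_height: float = 0.0
    coverslip_radius: float = 6.5e-3  # 13 mm coverslip
    pedestal_radius: float | None = None  # default: coverslip_radius
    clearance_min: float = 1e-3

    def __post_init__(self) -> None:
        if self.pedestal_radius is None:
            self.pedestal_radius = self.coverslip_radius
        for name in (
            "chamber_radius",
            "chamber_depth",
            "port_radius",
            "port_center_height",
            "coverslip_radius",
            "pedestal_radius",
            "clearance_min",
        ):
            v = getattr(self, name)
            if not (v > 0):
                raise ConfigurationError(name, f"must be strictly positive, got {v}")
        if self.insert_height < 0:
            raise ConfigurationError("insert_height", "must be >= 0")
        if self.insert_height + self.clearance_min > self.chamber_depth * (1 + 1e-12):
            raise ConfigurationError(
                "insert_height",
                f"insert_height + clearance_min ({self.insert_height} + "
                f"{self.clearance_min}) exceeds chamber_depth "
                f"({self.chamber_depth}); no fluid layer above the cells",
            )
        if self.pedestal_radius < self.coverslip_radius:
            raise ConfigurationError(
                "pedestal_radius", "must be >= coverslip_radius"
            )
        if self.chamber_radius <= self.pedestal_radius:
            raise ConfigurationError(
                "chamber_radius", "must exceed pedestal_radius"
            )
        if self.port_center_height + self.port_radius > self.chamber_depth:
            raise ConfigurationError(
                "port_center_height", "port extends above the chamber lid"
            )
        if self.port_center_height - self.port_radius < 0:
            raise ConfigurationError(
                "port_center_height", "port extends below the chamber base"
            )

    @property
    def cell_surface_height(self) -> float:
        """z of the plane carrying the cell monolayer (pedestal top)."""
        return self.insert_height


@dataclass
class FluidProperties:
    """Culture-medium properties at 37 degC (aqueous literature values)."""

    density: float = 993.0  # kg/m^3
    dynamic_viscosity: float = 0.7e-3  # Pa s
    oxygen_diffusivity: float = 3.0e-9  # m^2/s

    def __post_init__(self) -> None:
        for name in ("density", "dynamic_viscosity", "oxygen_diffusivity"):
            v = getattr(self, name)
            if not (v > 0):
                raise ConfigurationError(name, f"must be strictly positive, got {v}")


@dataclass
class OxygenKinetics:
    """Michaelis-Menten oxygen uptake by the monolayer.

    ``vmax_per_cell`` and ``km`` are external inputs: the source literature
    for hepatocyte kinetics spans orders of magnitude and the values shipped
    here are the ones under which the simulator's design outputs were
    anchored (see the methods note).  Override freely from the config file.
    """

    vmax_per_cell: float = 1.25e-17  # mol/(cell s)
    km: float = 5.0e-3  # mol/m^3
    cell_count: float = 1e6  # cells seeded per coverslip

    def __post_init__(self) -> None:
        if self.vmax_per_cell < 0:
            raise ConfigurationError("vmax_per_cell", "must be >= 0")
        if not (self.km > 0):
            raise ConfigurationError("km", "must be strictly positive")
        if not (self.cell_count > 0):
            raise ConfigurationError("cell_count", "must be strictly positive")

    def areal_density(self, coverslip_radius: float) -> float:
        """Cells per m^2 of coverslip: cell_count / (pi r^2)."""
        return self.cell_count / (math.pi * coverslip_radius**2)


@dataclass
class NumericalSettings:
    """Discretisation and nonlinear-iteration controls."""

    nonlinear_tol: float = 1e-8  # relative residual for Picard loops
    max_iterations: int = 50
    inertia: bool = False  # include the convective momentum term (Picard)
    re_warning_threshold: float = 100.0
    cells_across: int = 32  # target cells across the chamber depth, level 0
    surface_layer_scale: float = 5e-4  # m, near-surface boundary-layer scale
    surface_layer_fraction: float = 0.05  # smallest element <= fraction*scale

    def __post_init__(self) -> None:
        if not (0 < self.nonlinear_tol < 1):
            raise ConfigurationError("nonlinear_tol", "must be in (0, 1)")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations", "must be >= 1")
        if self.cells_across < 4:
            raise ConfigurationError("cells_across", "must be >= 4")
        if not (0 < self.surface_layer_fraction <= 1):
            raise ConfigurationError("surface_layer_fraction", "must be in (0, 1]")
        if not (self.surface_layer_scale > 0):
            raise ConfigurationError("surface_layer_scale", "must be positive")


@dataclass
class CultureConfig:
    """Complete description of one perfused-culture configuration."""

    flow_rate: float = 2.5e-9  # m^3/s (150 ul/min)
    inlet_oxygen: float = 0.21  # mol/m^3 (21 % O2, air-equilibrated)
    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    kinetics: OxygenKinetics = field(default_factory=OxygenKinetics)
    numerics: NumericalSettings = field(default_factory=NumericalSettings)

    def __post_init__(self) -> None:
        if self.flow_rate < 0:
            raise ConfigurationError("flow_rate", "must be >= 0")
        if not (0 <= self.inlet_oxygen <= C_REF):
            raise ConfigurationError(
                "inlet_oxygen", f"must lie in [0, {C_REF}] mol/m^3"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def areal_density(self) -> float:
        """Cell areal density sigma on the coverslip, cells/m^2."""
        return self.kinetics.areal_density(self.geometry.coverslip_radius)

    @property
    def sigma_vmax(self) -> float:
        """Maximum areal uptake flux sigma*Vmax, mol/(m^2 s)."""
        return self.areal_density * self.kinetics.vmax_per_cell

    @property
    def inlet_velocity(self) -> float:
        """Mean inlet velocity: flow rate over the circular port section."""
        return self.flow_rate / (math.pi * self.geometry.port_radius**2)

    @property
    def inlet_flux_2d(self) -> float:
        """Per-unit-width volumetric flux carried by the 2D section, m^2/s."""
        return self.inlet_velocity * 2.0 * self.geometry.port_radius

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "culture": {
                "flow_rate": self.flow_rate,
                "inlet_oxygen": self.inlet_oxygen,
            },
            "geometry": dataclasses.asdict(self.geometry),
            "fluid": dataclasses.asdict(self.fluid),
            "kinetics": dataclasses.asdict(self.kinetics),
            "numerics": dataclasses.asdict(self.numerics),
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "CultureConfig":
        known = {"culture", "geometry", "fluid", "kinetics", "numerics"}
        for key in data:
            if key not in known:
                warnings.warn(f"unknown config section {key!r} ignored", ConfigWarning)
        kwargs: dict[str, Any] = {}
        culture = dict(data.get("culture", {}))
        _warn_unknown(culture, {"flow_rate", "inlet_oxygen"}, "culture")
        if "flow_rate" in culture:
            kwargs["flow_rate"] = parse_flow_rate(culture["flow_rate"], "flow_rate")
        if "inlet_oxygen" in culture:
            kwargs["inlet_oxygen"] = _as_float(culture["inlet_oxygen"], "inlet_oxygen")

        geo = dict(data.get("geometry", {}))
        geo_fields = {f.name for f in dataclasses.fields(ChamberGeometry)}
        _warn_unknown(geo, geo_fields, "geometry")
        geo_kwargs = {
            k: parse_length(v, k) for k, v in geo.items()
            if k in geo_fields and v is not None
        }
        kwargs["geometry"] = ChamberGeometry(**geo_kwargs)

        kwargs["fluid"] = _load_section(data, "fluid", FluidProperties)
        kwargs["kinetics"] = _load_section(data, "kinetics", OxygenKinetics)
        kwargs["numerics"] = _load_section(data, "numerics", NumericalSettings)
        return cls(**kwargs)


def _as_float(value: Any, name: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigurationError(name, f"expected a number, got {value!r}")
    return float(value)


def _warn_unknown(section: dict, known: set[str], name: str) -> None:
    for key in section:
        if key not in known:
            warnings.warn(f"unknown key {name}.{key!r} ignored", ConfigWarning)


def _load_section(data: dict, name: str, cls):
    section = dict(data.get(name, {}))
    fields = {f.name: f for f in dataclasses.fields(cls)}
    _warn_unknown(section, set(fields), name)
    kwargs = {}
    for k, v in section.items():
        if k not in fields:
            continue
        f = fields[k]
        if f.type in ("float", float):
            v = _as_float(v, f"{name}.{k}")
        elif f.type in ("int", int):
            if isinstance(v, bool) or not isinstance(v, int):
                raise ConfigurationError(f"{name}.{k}", f"expected an integer, got {v!r}")
        elif f.type in ("bool", bool):
            if not isinstance(v, bool):
                raise ConfigurationError(f"{name}.{k}", f"expected a boolean, got {v!r}")
        kwargs[k] = v
    return cls(**kwargs)


def build_geometry(params: dict[str, Any] | None = None, /, **overrides: Any) -> CultureConfig:
    """Build a validated :class:`CultureConfig` from partial settings.

    Accepts either a nested dict in the config-file schema or flat keyword
    overrides for any geometry/culture/fluid/kinetics field; omitted fields
    fall back to the documented defaults.

    >>> cfg = build_geometry(insert_height=7e-3)
    >>> cfg.geometry.cell_surface_height
    0.007
    """
    data: dict[str, Any] = {k: dict(v) for k, v in (params or {}).items()}
    sections = {
        "geometry": {f.name for f in dataclasses.fields(ChamberGeometry)},
        "fluid": {f.name for f in dataclasses.fields(FluidProperties)},
        "kinetics": {f.name for f in dataclasses.fields(OxygenKinetics)},
        "numerics": {f.name for f in dataclasses.fields(NumericalSettings)},
        "culture": {"flow_rate", "inlet_oxygen"},
    }
    for key, value in overrides.items():
        for section, names in sections.items():
            if key in names:
                data.setdefault(section, {})[key] = value
                break
        else:
            raise ConfigurationError(key, "unknown configuration field")
    return CultureConfig.from_dict(data)


def load_config(path) -> CultureConfig:
    """Load a YAML configuration file (unknown keys warn, bad types raise)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("<root>", "config file must be a mapping")
    return CultureConfig.from_dict(data)


def save_config(config: CultureConfig, path) -> None:
    """Write a config to YAML; a load round-trip reproduces it exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
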