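"""Scenario configuration records, TOML loading/writing and validation.

A simulation is described declaratively: geometry (membrane + pore),
electrolyte (species, temperature), a surface-charge configuration, the
applied bias, and numerical controls.  Geometry defaults are the canonical
system studied here: a 10 nm diameter pore in a 20 nm silicon nitride
membrane, 250 nm reservoirs, immersed in 10 mM KCl.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from .constants import CONSTANTS, MC_PER_M2, NM, PhysicalConstants


class ConfigurationError(KeyError):
    """A mandatory configuration key is missing or unknown."""


class ValidationError(ValueError):
    """A configuration value violates an invariant."""


CHARGE_CONFIGURATIONS = (
    "uncharged",
    "a_uniform",
    "b_pore_only",
    "c_asymmetric",
    "custom",
)


@dataclass(frozen=True)
class SpeciesSpec:
    """One ionic species: charge number, diffusion coefficient, bulk level.

    Units: D in m^2/s, c_B in mol/m^3 (numerically equal to mM).
    """

    name: str
    charge_number: int
    diffusion_coefficient: float
    bulk_concentration: float

    def __post_init__(self) -> None:
        if self.charge_number == 0:
            raise ValidationError(f"species {self.name!r}: charge number must be nonzero")
        if self.diffusion_coefficient <= 0:
            raise ValidationError(
                f"species {self.name!r}: D must be positive, got {self.diffusion_coefficient}"
            )
        if self.bulk_concentration < 0:
            raise ValidationError(
                f"species {self.name!r}: bulk concentration must be >= 0, "
                f"got {self.bulk_concentration}"
            )


@dataclass(frozen=True)
class ElectrolyteSpec:
    """Electrolyte composition and temperature.

    The bulk must be electroneutral: sum_i z_i c_Bi = 0.
    """

    species: tuple[SpeciesSpec, ...]
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError(f"temperature must be positive, got {self.temperature} K")
        if not self.species:
            raise ValidationError("electrolyte must contain at least one species")
        net = sum(s.charge_number * s.bulk_concentration for s in self.species)
        scale = sum(abs(s.charge_number) * s.bulk_concentration for s in self.species)
        if scale > 0 and abs(net) > 1e-12 * scale:
            raise ValidationError(
                f"bulk electrolyte is not electroneutral: sum z_i c_Bi = {net} mol/m^3"
            )

    def ionic_strength(self) -> float:
        """0.5 * sum_i z_i^2 c_Bi, mol/m^3."""
        return 0.5 * sum(s.charge_number**2 * s.bulk_concentration for s in self.species)


def kcl_electrolyte(concentration: float, temperature: float = 298.15) -> ElectrolyteSpec:
    """Symmetric KCl electrolyte at `concentration` mol/m^3 (== mM).

    Diffusion coefficients: D(K+) = 1.95e-9 m^2/s, D(Cl-) = 2.03e-9 m^2/s.
    """
    return ElectrolyteSpec(
        species=(
            SpeciesSpec("K", +1, 1.95e-9, concentration),
            SpeciesSpec("Cl", -1, 2.03e-9, concentration),
        ),
        temperature=temperature,
    )


@dataclass(frozen=True)
class GeometrySpec:
    """Axisymmetric domain: two reservoirs and a membrane with a pore.

    ``opening_angle`` is the full cone angle in degrees (0 = cylinder).
    The small opening has diameter ``pore_diameter_small``; the large
    opening sits on ``large_opening_side``.  z = 0 at the left membrane
    face, z increases left -> right; the pore axis is r = 0.
    """

    membrane_thickness: float = 20 * NM
    pore_diameter_small: float = 10 * NM
    opening_angle: float = 0.0
    large_opening_side: str = "right"
    reservoir_depth: float = 250 * NM
    domain_radius: float = 250 * NM

    def __post_init__(self) -> None:
        if self.pore_diameter_small <= 0:
            raise ValidationError("pore diameter must be positive")
        if self.membrane_thickness <= 0:
            raise ValidationError("membrane thickness must be positive")
        if not (0 <= self.opening_angle < 90):
            raise ValidationError(
                f"opening angle must be in [0, 90) degrees, got {self.opening_angle}"
            )
        if self.large_opening_side not in ("left", "right"):
            raise ValidationError("large_opening_side must be 'left' or 'right'")
        if self.reservoir_depth <= 0 or self.domain_radius <= 0:
            raise ValidationError("reservoir depth and domain radius must be positive")
        if self.domain_radius <= self.large_diameter / 2:
            raise ValidationError("domain radius must exceed the large pore opening radius")

    @property
    def large_diameter(self) -> float:
        """Diameter of the large cone opening (== small diameter for a cylinder)."""
        return cone_large_diameter(
            self.pore_diameter_small, self.membrane_thickness, self.opening_angle
        )

    def wall_radius(self, z: float) -> float:
        """Pore-wall radius at axial position z within the membrane [0, L_m]."""
        t = math.tan(math.radians(self.opening_angle / 2))
        if self.large_opening_side == "right":
            return self.pore_diameter_small / 2 + z * t
        return self.pore_diameter_small / 2 + (self.membrane_thickness - z) * t


def cone_large_diameter(d: float, L_m: float, opening_angle: float) -> float:
    """Large-opening diameter of a conical pore: d + 2 L_m tan(angle/2).

    For the canonical 10 nm pore in a 20 nm membrane with a 20 degree full
    opening angle this gives ~17 nm.
    """
    if d <= 0 or L_m <= 0:
        raise ValidationError("pore diameter and membrane thickness must be positive")
    if not (0 <= opening_angle < 90):
        raise ValidationError(f"opening angle must be in [0, 90), got {opening_angle}")
    return d + 2 * L_m * math.tan(math.radians(opening_angle / 2))


@dataclass(frozen=True)
class ChargeSpec:
    """Declarative surface-charge configuration.

    ``configuration`` selects which water/nitride interface segments carry
    the fixed charge density ``sigma`` (C/m^2):

    - ``uncharged``:    nothing charged
    - ``a_uniform``:    pore wall and both membrane faces
    - ``b_pore_only``:  pore wall only
    - ``c_asymmetric``: left membrane face and the left half of the pore wall
    - ``custom``:       resolved by user code against the mesh
    """

    configuration: str = "uncharged"
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.configuration not in CHARGE_CONFIGURATIONS:
            raise ValidationError(
                f"unknown charge configuration {self.configuration!r}; "
                f"valid: {', '.join(CHARGE_CONFIGURATIONS)}"
            )


@dataclass(frozen=True)
class NumericalControls:
    """Numerical controls for the dual-time-step integration and the mesh.

    ``poisson_step_fraction`` is delta_t_P / tau_RC; ``transport_step_fraction``
    multiplies the diffusive stability bound dx_min^2 / D_max.  The steady-state
    loop stops when per-species plane currents are uniform within
    ``uniformity_tolerance`` of the total current (or of the estimated current
    at ``reference_voltage`` for zero-bias runs).
    """

    poisson_step_fraction: float = 1.0 / 40.0
    transport_step_fraction: float = 1.0 / 5.0
    rc_multiples: float = 20.0
    uniformity_tolerance: float = 0.005
    reference_voltage: float = 0.1
    min_element_size: float = 0.5 * NM
    mesh_growth_ratio: float = 1.3
    linear_solver_tolerance: float = 1e-10
    max_outer_iterations: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.poisson_step_fraction < 1):
            raise ValidationError("poisson_step_fraction must be in (0, 1)")
        if not (0 < self.transport_step_fraction <= 1):
            raise ValidationError("transport_step_fraction must be in (0, 1]")
        if self.uniformity_tolerance <= 0:
            raise ValidationError("uniformity_tolerance must be positive")
        if self.min_element_size <= 0:
            raise ValidationError("min_element_size must be positive")
        if self.mesh_growth_ratio <= 1:
            raise ValidationError("mesh_growth_ratio must exceed 1")
        if self.rc_multiples <= 0:
            raise ValidationError("rc_multiples must be positive")


#: Desk-scale mesh profiles. "coarse" resolves the 3 nm Debye layer with
#: ~3 cells and keeps one bias point in the minutes range; "fine" doubles
#: the wall resolution for convergence studies.
MESH_PROFILES = {
    "coarse": {"min_element_size": 1.0 * NM, "mesh_growth_ratio": 1.45},
    "default": {"min_element_size": 0.5 * NM, "mesh_growth_ratio": 1.3},
    "fine": {"min_element_size": 0.25 * NM, "mesh_growth_ratio": 1.2},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Complete declarative description of one simulation."""

    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    electrolyte: ElectrolyteSpec = field(default_factory=lambda: kcl_electrolyte(10.0))
    charges: ChargeSpec = field(default_factory=ChargeSpec)
    V_left: float = 0.0
    V_right: float = 0.0
    controls: NumericalControls = field(default_factory=NumericalControls)
    permittivity_water: float = 78.4
    permittivity_membrane: float = 7.5
    constants: PhysicalConstants = field(default_factory=lambda: CONSTANTS)

    def __post_init__(self) -> None:
        if not (self.permittivity_water > self.permittivity_membrane > 1):
            raise ValidationError(
                "expected eps_r(water) > eps_r(membrane) > 1, got "
                f"{self.permittivity_water}, {self.permittivity_membrane}"
            )

    @property
    def bias(self) -> float:
        """Applied bias V_L - V_R in volts."""
        return self.V_left - self.V_right

    def with_bias(self, bias: float) -> "SimulationConfig":
        """Copy with V_left = bias, V_right = 0."""
        return replace(self, V_left=bias, V_right=0.0)


# ---------------------------------------------------------------------------
# TOML serialization
# ---------------------------------------------------------------------------

_MANDATORY_SECTIONS = ("geometry", "electrolyte", "charges", "bias", "numerics")


def _get(section: dict, sec_name: str, key: str, default=None):
    if key in section:
        return section[key]
    if default is None:
        raise ConfigurationError(f"missing mandatory key [{sec_name}] {key}")
    return default


def load_config(path: str | Path) -> SimulationConfig:
    """Load a scenario configuration from a TOML file.

    Interface units: geometry lengths in nm, concentrations in mM, surface
    charge in mC/m^2, voltages in V, temperature in K.  A ``scenario`` key
    at top level selects a named preset whose values individual keys
    override.
    """
    path = Path(path)
    with path.open("rb") as fh:
        raw = tomllib.load(fh)

    if "scenario" in raw:
        from .scenarios import preset

    base = preset(raw["scenario"]).config if "scenario" in raw else SimulationConfig()

    geo_raw = raw.get("geometry", {})
    g = base.geometry
    geometry = GeometrySpec(
        membrane_thickness=geo_raw.get("membrane_thickness_nm", g.membrane_thickness / NM) * NM,
        pore_diameter_small=geo_raw.get("pore_diameter_nm", g.pore_diameter_small / NM) * NM,
        opening_angle=geo_raw.get("opening_angle_deg", g.opening_angle),
        large_opening_side=geo_raw.get("large_opening_side", g.large_opening_side),
        reservoir_depth=geo_raw.get("reservoir_depth_nm", g.reservoir_depth / NM) * NM,
        domain_radius=geo_raw.get("domain_radius_nm", g.domain_radius / NM) * NM,
    )

    el_raw = raw.get("electrolyte", {})
    if "species" in el_raw:
        species = tuple(
            SpeciesSpec(
                name=_get(s, "electrolyte.species", "name"),
                charge_number=int(_get(s, "electrolyte.species", "z")),
                diffusion_coefficient=float(_get(s, "electrolyte.species", "D_m2_per_s")),
                bulk_concentration=float(_get(s, "electrolyte.species", "c_mM")),
            )
            for s in el_raw["species"]
        )
        electrolyte = ElectrolyteSpec(
            species=species,
            temperature=el_raw.get("temperature_K", base.electrolyte.temperature),
        )
    elif "kcl_mM" in el_raw:
        electrolyte = kcl_electrolyte(
            float(el_raw["kcl_mM"]),
            el_raw.get("temperature_K", base.electrolyte.temperature),
        )
    else:
        electrolyte = base.electrolyte

    ch_raw = raw.get("charges", {})
    charges = ChargeSpec(
        configuration=ch_raw.get("configuration", base.charges.configuration),
        sigma=ch_raw.get("sigma_mC_per_m2", base.charges.sigma / MC_PER_M2) * MC_PER_M2,
    )

    bias_raw = raw.get("bias", {})
    V_left = bias_raw.get("V_left", base.V_left)
    V_right = bias_raw.get("V_right", base.V_right)

    num_raw = raw.get("numerics", {})
    c = base.controls
    controls = NumericalControls(
        poisson_step_fraction=num_raw.get("poisson_step_fraction", c.poisson_step_fraction),
        transport_step_fraction=num_raw.get(
            "transport_step_fraction", c.transport_step_fraction
        ),
        rc_multiples=num_raw.get("rc_multiples", c.rc_multiples),
        uniformity_tolerance=num_raw.get("uniformity_tolerance", c.uniformity_tolerance),
        reference_voltage=num_raw.get("reference_voltage", c.reference_voltage),
        min_element_size=num_raw.get("min_element_size_nm", c.min_element_size / NM) * NM,
        mesh_growth_ratio=num_raw.get("mesh_growth_ratio", c.mesh_growth_ratio),
        linear_solver_tolerance=num_raw.get(
            "linear_solver_tolerance", c.linear_solver_tolerance
        ),
        max_outer_iterations=num_raw.get("max_outer_iterations", c.max_outer_iterations),
    )

    return SimulationConfig(
        geometry=geometry,
        electrolyte=electrolyte,
        charges=charges,
        V_left=V_left,
        V_right=V_right,
        controls=controls,
        permittivity_water=raw.get("permittivity_water", base.permittivity_water),
        permittivity_membrane=raw.get("permittivity_membrane", base.permittivity_membrane),
    )


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v) + '"'


def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a configuration as TOML so that load_config round-trips it."""
    g, e, ch, n = config.geometry, config.electrolyte, config.charges, config.controls
    lines = [
        f"permittivity_water = {_toml_value(config.permittivity_water)}",
        f"permittivity_membrane = {_toml_value(config.permittivity_membrane)}",
        "",
        "[geometry]",
        f"membrane_thickness_nm = {_toml_value(g.membrane_thickness / NM)}",
        f"pore_diameter_nm = {_toml_value(g.pore_diameter_small / NM)}",
        f"opening_angle_deg = {_toml_value(g.opening_angle)}",
        f"large_opening_side = {_toml_value(g.large_opening_side)}",
        f"reservoir_depth_nm = {_toml_value(g.reservoir_depth / NM)}",
        f"domain_radius_nm = {_toml_value(g.domain_radius / NM)}",
        "",
        "[electrolyte]",
        f"temperature_K = {_toml_value(e.temperature)}",
    ]
    for s in e.species:
        lines += [
            "[[electrolyte.species]]",
            f"name = {_toml_value(s.name)}",
            f"z = {_toml_value(s.charge_number)}",
            f"D_m2_per_s = {_toml_value(s.diffusion_coefficient)}",
            f"c_mM = {_toml_value(s.bulk_concentration)}",
        ]
    lines += [
        "",
        "[charges]",
        f"configuration = {_toml_value(ch.configuration)}",
        f"sigma_mC_per_m2 = {_toml_value(ch.sigma / MC_PER_M2)}",
        "",
        "[bias]",
        f"V_left = {_toml_value(config.V_left)}",
        f"V_right = {_toml_value(config.V_right)}",
        "",
        "[numerics]",
        f"poisson_step_fraction = {_toml_value(n.poisson_step_fraction)}",
        f"transport_step_fraction = {_toml_value(n.transport_step_fraction)}",
        f"rc_multiples = {_toml_value(n.rc_multiples)}",
        f"uniformity_tolerance = {_toml_value(n.uniformity_tolerance)}",
        f"reference_voltage = {_toml_value(n.reference_voltage)}",
        f"min_element_size_nm = {_toml_value(n.min_element_size / NM)}",
        f"mesh_growth_ratio = {_toml_value(n.mesh_growth_ratio)}",
        f"linear_solver_tolerance = {_toml_value(n.linear_solver_tolerance)}",
        f"max_outer_iterations = {_toml_value(n.max_outer_iterations)}",
        "",
    ]
    Path(path).write_text("\n".join(lines))
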