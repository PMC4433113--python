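"""Closed-form reference quantities for validation and convergence scales.

These are the textbook electrochemistry results the solver is checked
against: Debye screening length, Nernst-Einstein conductivity, the RC time
constant of the simulated solution column and membrane capacitor, the
Gouy-Chapman double layer of a flat charged plane, and the pore + access
resistance estimate used to normalize zero-bias convergence.

All functions are pure and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ElectrolyteSpec, GeometrySpec, ValidationError
from .constants import CONSTANTS, PhysicalConstants


@dataclass(frozen=True)
class OracleContext:
    """Bundle of electrolyte, geometry and permittivities for the oracles."""

    electrolyte: ElectrolyteSpec
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    permittivity_water: float = 78.4
    permittivity_membrane: float = 7.5
    constants: PhysicalConstants = field(default_factory=lambda: CONSTANTS)


def debye_length(ctx: OracleContext) -> float:
    """Debye screening length kappa^-1 in metres.

    kappa^-1 = sqrt(eps0 epsr_w k_B T / sum_i (z_i e)^2 c_Bi N_A).
    ~3 nm for 10 mM KCl at room temperature.
    """
    k = ctx.constants
    denom = sum(
        (s.charge_number * k.elementary_charge) ** 2 * s.bulk_concentration * k.avogadro
        for s in ctx.electrolyte.species
    )
    if denom <= 0:
        raise ValidationError("zero ionic strength: Debye length undefined")
    num = k.vacuum_permittivity * ctx.permittivity_water * k.boltzmann * ctx.electrolyte.temperature
    return math.sqrt(num / denom)


def intermediate_diffusion(D_K: float, D_Cl: float) -> float:
    """Co-diffusion coefficient D_int = 2 D_K D_Cl / (D_K + D_Cl).

    The harmonic-mean diffusivity governing relaxation of the common-mode
    (chargeless) concentration perturbation of a binary electrolyte.
    """
    if D_K < 0 or D_Cl < 0:
        raise ValidationError("diffusion coefficients must be nonnegative")
    if D_K + D_Cl == 0:
        return 0.0
    return 2 * D_K * D_Cl / (D_K + D_Cl)


def codiffusion_time(L: float, D_int: float) -> float:
    """Diffusive relaxation time L^2 / D_int for a common-mode disturbance
    to travel a distance L (~30 us for 250 nm reservoirs in KCl)."""
    if L <= 0 or D_int <= 0:
        raise ValidationError("length and diffusivity must be positive")
    return L * L / D_int


def conductivity(ctx: OracleContext) -> float:
    """Bulk electrolyte conductivity from the Nernst-Einstein relation.

    sigma = (F^2 / (R T)) sum_i z_i^2 c_Bi D_i, in S/m.  Computed from the
    same diffusion coefficients the transport model uses, for internal
    consistency (~0.149 S/m for 10 mM KCl).
    """
    k = ctx.constants
    RT = k.gas_constant * ctx.electrolyte.temperature
    return (k.faraday**2 / RT) * sum(
        s.charge_number**2 * s.bulk_concentration * s.diffusion_coefficient
        for s in ctx.electrolyte.species
    )


def membrane_RC(ctx: OracleContext) -> tuple[float, float, float]:
    """Solution-column resistance, membrane capacitance and tau = R C.

    R is the resistance of the two reservoir columns in series over the full
    domain cross-section; C is the parallel-plate capacitance of the membrane
    over that cross-section (pore area neglected).  For the canonical domain
    (250 nm radius and reservoirs, 20 nm membrane, 10 mM KCl) this gives
    C ~ 0.65 fF and tau ~ 1e-8 s.
    """
    g = ctx.geometry
    sigma = conductivity(ctx)
    if sigma <= 0:
        raise ValidationError("zero conductivity")
    area = math.pi * g.domain_radius**2
    R = 2 * g.reservoir_depth / (sigma * area)
    C = ctx.constants.vacuum_permittivity * ctx.permittivity_membrane * area / g.membrane_thickness
    return R, C, R * C


def pore_access_resistance(ctx: OracleContext) -> float:
    """Pore resistance plus two-sided access (convergence) resistance, Ohm.

    R_pore = 4 L_m / (sigma pi d^2) with d the mean pore diameter for cones;
    R_access = 1 / (sigma d) for both hemispherical access regions together.
    """
    g = ctx.geometry
    sigma = conductivity(ctx)
    if sigma <= 0:
        raise ValidationError("zero conductivity")
    d = 0.5 * (g.pore_diameter_small + g.large_diameter)
    R_pore = 4 * g.membrane_thickness / (sigma * math.pi * d**2)
    R_access = 1.0 / (sigma * d)
    return R_pore + R_access


def ion_spacing(ctx: OracleContext) -> float:
    """Mean inter-ion spacing (total ion density)^(-1/3), metres.

    ~4 nm at 10 mM KCl counting both species: ions are discrete on the scale
    of the Debye length at this concentration.
    """
    k = ctx.constants
    density = sum(s.bulk_concentration for s in ctx.electrolyte.species) * k.avogadro
    if density <= 0:
        raise ValidationError("zero ion density")
    return density ** (-1.0 / 3.0)


@dataclass(frozen=True)
class GouyChapmanProfile:
    """1D equilibrium double layer at a flat charged plane in a 1:1 electrolyte."""

    surface_potential: float          # V, relative to bulk
    debye_length: float               # m
    sigma: float                      # C/m^2
    bulk_concentration: float         # mol/m^3 per species
    temperature: float                # K
    constants: PhysicalConstants

    def potential(self, x: np.ndarray) -> np.ndarray:
        """Potential phi(x) at distance x from the plane (Gouy-Chapman decay)."""
        x = np.asarray(x, dtype=float)
        k = self.constants
        Vt = k.boltzmann * self.temperature / k.elementary_charge
        gamma = math.tanh(self.surface_potential / (4 * Vt))
        g = gamma * np.exp(-x / self.debye_length)
        return 2 * Vt * np.log((1 + g) / (1 - g)) if gamma != 0 else np.zeros_like(x)

    def concentration(self, x: np.ndarray, z: int) -> np.ndarray:
        """Boltzmann concentration profile of the species with charge number z."""
        k = self.constants
        Vt = k.boltzmann * self.temperature / k.elementary_charge
        return self.bulk_concentration * np.exp(-z * self.potential(x) / Vt)


def gouy_chapman_profile(sigma_S: float, ctx: OracleContext) -> GouyChapmanProfile:
    """Closed-form Gouy-Chapman double layer for a flat plane at sigma_S.

    The surface potential follows from the Grahame equation
    sigma = sqrt(8 eps0 epsr_w k_B T c_B N_A) sinh(e phi0 / (2 k_B T));
    the returned profile evaluates the full nonlinear potential decay and the
    Boltzmann concentration profiles.  Only symmetric 1:1 electrolytes are
    supported.
    """
    species = ctx.electrolyte.species
    zs = sorted(s.charge_number for s in species)
    if len(species) != 2 or zs != [-1, 1]:
        raise ValidationError("Gouy-Chapman oracle requires a symmetric 1:1 electrolyte")
    c_B = species[0].bulk_concentration
    k = ctx.constants
    T = ctx.electrolyte.temperature
    Vt = k.boltzmann * T / k.elementary_charge
    prefac = math.sqrt(
        8 * k.vacuum_permittivity * ctx.permittivity_water * k.boltzmann * T * c_B * k.avogadro
    )
    phi0 = 2 * Vt * math.asinh(sigma_S / prefac) if prefac > 0 else 0.0
    return GouyChapmanProfile(
        surface_potential=phi0,
        debye_length=debye_length(ctx),
        sigma=sigma_S,
        bulk_concentration=c_B,
        temperature=T,
        constants=k,
    )


def grahame_sigma(phi0: float, ctx: OracleContext) -> float:
    """Surface charge density from the surface potential (Grahame equation)."""
    species = ctx.electrolyte.species
    c_B = species[0].bulk_concentration
    k = ctx.constants
    T = ctx.electrolyte.temperature
    Vt = k.boltzmann * T / k.elementary_charge
    prefac = math.sqrt(
        8 * k.vacuum_permittivity * ctx.permittivity_water * k.boltzmann * T * c_B * k.avogadro
    )
    return prefac * math.sinh(phi0 / (2 * Vt))


def oracle_table(ctx: OracleContext) -> list[tuple[str, float, str]]:
    """(name, value, units) rows for the canonical analytic quantities."""
    R, C, tau = membrane_RC(ctx)
    D = {s.name: s.diffusion_coefficient for s in ctx.electrolyte.species}
    D_int = intermediate_diffusion(D.get("K", 0.0), D.get("Cl", 0.0))
    rows = [
        ("debye_length", debye_length(ctx), "m"),
        ("conductivity", conductivity(ctx), "S/m"),
        ("solution_resistance", R, "Ohm"),
        ("membrane_capacitance", C, "F"),
        ("rc_time_constant", tau, "s"),
        ("pore_plus_access_resistance", pore_access_resistance(ctx), "Ohm"),
        ("ion_spacing", ion_spacing(ctx), "m"),
        ("intermediate_diffusion", D_int, "m^2/s"),
    ]
    if D_int > 0:
        rows.append(
            ("codiffusion_time", codiffusion_time(ctx.geometry.reservoir_depth, D_int), "s")
        )
    return rows
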