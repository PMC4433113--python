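"""Physical constants and unit helpers.

All internal computation is in SI units (m, s, V, mol/m^3, C/m^2, ...).
Interface layers (config files, presets, CLI) accept the field's customary
units -- nm, mV, mM, mC/m^2 -- and convert exactly once on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA physical constants used throughout the solver.

    Attributes
    ----------
    faraday : float
        Faraday constant F, C/mol.
    elementary_charge : float
        Elementary charge e, C.
    boltzmann : float
        Boltzmann constant k_B, J/K.
    avogadro : float
        Avogadro constant N_A, 1/mol.
    vacuum_permittivity : float
        Electric constant eps_0, F/m.
    """

    faraday: float = 96485.33212
    elementary_charge: float = 1.602176634e-19
    boltzmann: float = 1.380649e-23
    avogadro: float = 6.02214076e23
    vacuum_permittivity: float = 8.8541878128e-12

    def __post_init__(self) -> None:
        vals = (
            self.faraday,
            self.elementary_charge,
            self.boltzmann,
            self.avogadro,
            self.vacuum_permittivity,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all physical constants must be strictly positive")
        rel = abs(self.faraday - self.elementary_charge * self.avogadro) / self.faraday
        if rel > 1e-6:
            raise ValueError(
                f"inconsistent constants: F != e*N_A (relative error {rel:.2e})"
            )

    @property
    def gas_constant(self) -> float:
        """Molar gas constant R = k_B * N_A, J/(mol K)."""
        return self.boltzmann * self.avogadro


#: Module-level default constant set.
CONSTANTS = PhysicalConstants()


def thermal_voltage(T: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """Thermal voltage k_B*T/e in volts (~25.7 mV at room temperature)."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    return constants.boltzmann * T / constants.elementary_charge


# Unit conversions: applied exactly once at the configuration boundary.
NM = 1e-9          # nm -> m
MV = 1e-3          # mV -> V
MM = 1.0           # mmol/L == mol/m^3 (numerically identical)
MC_PER_M2 = 1e-3   # mC/m^2 -> C/m^2
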