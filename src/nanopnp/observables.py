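"""Derived quantities: plane currents, mode fluxes, electrochemical
potentials, polarization charges, I-V curves and ion counts.

The convergence and reporting surface of a simulation is the set of axial
planes parallel to the membrane: at true steady state the current carried
by EACH ion species is the same through every plane; during the transient
only the total (charge) current is uniform once the membrane capacitor has
charged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ValidationError
from .constants import CONSTANTS
from .mesh import LEFT_FACE, RIGHT_FACE, Mesh
from .poisson import PoissonSolver, interface_normal_fields
from .transport import TransportSystem


@dataclass
class CurrentProfile:
    """Per-species and total current through the axial planes.

    ``currents`` maps species name -> (P,) array of amperes; ``z`` holds the
    plane positions.  The total is the exact per-plane sum of the species
    contributions.
    """

    z: np.ndarray
    currents: dict[str, np.ndarray]

    @property
    def total(self) -> np.ndarray:
        return np.sum(list(self.currents.values()), axis=0)

    def species_spread(self) -> dict[str, float]:
        """max_z I_i(z) - min_z I_i(z) per species, A."""
        return {name: float(I.max() - I.min()) for name, I in self.currents.items()}


def plane_positions(system: TransportSystem) -> np.ndarray:
    """Axial plane positions: interior node z-levels of the mesh."""
    z = np.unique(system.mesh.nodes[:, 1])
    return z[1:-1]


def plane_currents(
    system: TransportSystem, V: np.ndarray, concentrations: list[np.ndarray]
) -> CurrentProfile:
    """Current of each species through every axial plane.

    I_i(z) = F z_i * sum of SG facet flows crossing the plane, signed in the
    +z direction.
    """
    zs = plane_positions(system)
    if len(zs) == 0:
        raise ValidationError("mesh has no interior axial planes")
    z0 = system.centroid[system.face_cells[:, 0], 1]
    z1 = system.centroid[system.face_cells[:, 1], 1]
    sign = np.sign(z1 - z0)
    lo = np.minimum(z0, z1)
    hi = np.maximum(z0, z1)
    F = system.constants.faraday
    currents: dict[str, np.ndarray] = {}
    # each face contributes to every plane strictly between its two cell
    # centroids; accumulate via a difference array over the sorted planes
    idx_lo = np.searchsorted(zs, lo, side="right")
    idx_hi = np.searchsorted(zs, hi, side="left")
    # drop planes crossed by no liquid facet (e.g. inside a pore-less slab)
    count = np.zeros(len(zs) + 1)
    np.add.at(count, idx_lo, 1.0)
    np.add.at(count, idx_hi, -1.0)
    crossed = np.cumsum(count[:-1]) > 0
    if not crossed.all():
        zs = zs[crossed]
        if len(zs) == 0:
            raise ValidationError("no axial plane intersects the liquid")
        idx_lo = np.searchsorted(zs, lo, side="right")
        idx_hi = np.searchsorted(zs, hi, side="left")
    for i, s in enumerate(system.species):
        Q = system.face_fluxes(V, concentrations[i], i)
        contrib = F * s.charge_number * Q * sign
        diff = np.zeros(len(zs) + 1)
        np.add.at(diff, idx_lo, contrib)
        np.add.at(diff, idx_hi, -contrib)
        currents[s.name] = np.cumsum(diff[:-1])
    return CurrentProfile(z=zs, currents=currents)


def midplane_current(profile: CurrentProfile, z_mid: float) -> dict[str, float]:
    """Species and total current at the plane nearest ``z_mid``."""
    k = int(np.argmin(np.abs(profile.z - z_mid)))
    out = {name: float(I[k]) for name, I in profile.currents.items()}
    out["total"] = float(profile.total[k])
    return out


# ---------------------------------------------------------------------------


def mode_decomposition(j_K: np.ndarray, j_Cl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Common- and differential-mode fluxes of a binary electrolyte.

    j_c = (j_K + j_Cl)/2 carries no charge (co-diffusion); j_d = (j_K - j_Cl)/2
    carries half the total charge flux.  The species fluxes reconstruct
    exactly as j_K = j_c + j_d and j_Cl = j_c - j_d.
    """
    j_K = np.asarray(j_K, dtype=float)
    j_Cl = np.asarray(j_Cl, dtype=float)
    if j_K.shape != j_Cl.shape:
        raise ValidationError("mode decomposition requires fluxes on the same mesh")
    return 0.5 * (j_K + j_Cl), 0.5 * (j_K - j_Cl)


def electrochemical_potential(
    system: TransportSystem,
    V: np.ndarray,
    c: np.ndarray,
    species_idx: int,
) -> np.ndarray:
    """Per-cell electrochemical energy z_i e V + k_B T ln(c_i / c_Bi), joules.

    Zero wherever the species sits at bulk concentration and zero voltage;
    uniform at equilibrium (Boltzmann cancellation).  Cells with c <= 0 are
    masked with NaN.
    """
    s = system.species[species_idx]
    k = system.constants
    Vc = system.cell_voltage(V)
    out = np.full(system.n_cells, np.nan)
    ok = c > 0
    out[ok] = (
        s.charge_number * k.elementary_charge * Vc[ok]
        + k.boltzmann * system.temperature * np.log(c[ok] / s.bulk_concentration)
    )
    return out


# ---------------------------------------------------------------------------


def polarization_charge_density(
    V: np.ndarray,
    mesh: Mesh,
    solver: PoissonSolver,
    epsr_membrane: float,
    eps0: float = CONSTANTS.vacuum_permittivity,
) -> np.ndarray:
    """Voltage-induced polarization charge per interface edge, C/m^2.

    sigma_pol = -eps0 epsr_m E_perp,membrane (normal liquid -> membrane):
    the displacement field driven into the dielectric by the applied bias,
    which the electrolyte's double layer must screen in addition to the
    fixed chemical charge sigma_S.  Zero at zero-bias equilibrium (no field
    penetrates the membrane); for a flat membrane region carrying a voltage
    drop dV it equals eps0 epsr_m dV / L_m in magnitude -- the charged
    parallel-plate capacitor.  By Gauss's law the diffuse-layer charge per
    unit area at the interface is -(sigma_S + sigma_pol).
    """
    _, E_mem, _ = interface_normal_fields(V, mesh, solver)
    return -eps0 * epsr_membrane * E_mem


def face_average_polarization(
    mesh: Mesh, sigma_pol: np.ndarray, side: str, outer_fraction: float = 0.5
) -> float:
    """Area-weighted average sigma_pol over the outer part of a membrane face.

    ``side`` is 'left' or 'right'; only edges with midpoint radius above
    ``outer_fraction`` of the domain radius enter (far from the pore, where
    the interface is effectively a flat plane).
    """
    want = LEFT_FACE if side == "left" else RIGHT_FACE
    kinds = mesh.interface_kind
    ie = mesh.interface_edges
    r_mid = 0.5 * (
        mesh.nodes[mesh.edges[ie, 0], 0] + mesh.nodes[mesh.edges[ie, 1], 0]
    )
    r_max = mesh.nodes[:, 0].max()
    pick = np.array(
        [k == want and rm > outer_fraction * r_max for k, rm in zip(kinds, r_mid)]
    )
    if not pick.any():
        raise ValidationError(f"no {side} membrane-face edges in the outer region")
    areas = mesh.edge_revolved_area(ie[pick])
    return float(np.sum(sigma_pol[pick] * areas) / np.sum(areas))


# ---------------------------------------------------------------------------


@dataclass
class IVCurve:
    """Steady (or fixed-time) current-voltage characteristic.

    ``G`` is the chord conductance I/V (NaN at V = 0); ``g`` the differential
    conductance dI/dV by central differences on the sweep grid; the
    rectification ratio G(+V)/G(-V) is defined for positive biases with a
    matching negative point.
    """

    V: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if len(self.V) < 2:
            raise ValidationError("an I-V curve needs at least two bias points")
        if len(np.unique(self.V)) != len(self.V):
            raise ValidationError("duplicate bias points in I-V sweep")
        order = np.argsort(self.V)
        self.V = self.V[order]
        self.I = self.I[order]

    @property
    def G(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.V != 0, self.I / self.V, np.nan)

    @property
    def g(self) -> np.ndarray:
        return np.gradient(self.I, self.V)

    def rectification_ratio(self) -> dict[float, float]:
        """G(+V)/G(-V) for every positive bias with a matching negative one."""
        out: dict[float, float] = {}
        G = self.G
        for i, v in enumerate(self.V):
            if v <= 0:
                continue
            match = np.nonzero(np.isclose(self.V, -v, rtol=1e-9, atol=1e-15))[0]
            if len(match):
                out[float(v)] = float(G[i] / G[match[0]])
        return out


def ions_in_volume(
    system: TransportSystem,
    concentrations: list[np.ndarray],
    z_range: tuple[float, float] | None = None,
    r_max: float | None = None,
) -> float:
    """Number of ions (all species) in a cylindrical sub-volume.

    N = N_A * sum_i integral c_i dV over the cells whose centroids fall in
    ``z_range`` x [0, r_max].  Defaults to the pore region: the membrane's
    axial extent at all radii (the liquid there is exactly the pore).
    """
    mesh = system.mesh
    if z_range is None:
        if mesh.membrane_z is None:
            raise ValidationError("no membrane: specify z_range explicitly")
        z_range = mesh.membrane_z
    cz = system.centroid[:, 1]
    cr = system.centroid[:, 0]
    pick = (cz >= z_range[0]) & (cz <= z_range[1])
    if r_max is not None:
        pick &= cr <= r_max
    vol = system.volume[pick]
    total = 0.0
    for c in concentrations:
        total += float(np.sum(c[pick] * vol))
    return total * system.constants.avogadro
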