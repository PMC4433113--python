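"""Finite-volume ion transport with Scharfetter-Gummel fluxes.

Concentrations are piecewise constant, one value per liquid triangle (the
triangles are the finite-volume cells).  The Nernst-Planck flux between two
adjacent cells uses exponential fitting (Scharfetter-Gummel): it is exact
for the 1D two-point drift-diffusion problem, reduces to central diffusion
at zero field, and vanishes identically at Boltzmann-equilibrium
concentration ratios.  Facet areas are the surfaces of revolution of the
shared edges (2 pi r_mid * length); the drift potential difference is the
piecewise-linear voltage evaluated at the two cell centroids.

Boundary conditions: bulk Dirichlet concentrations in the cell layer
touching the reservoir far ends; zero flux at the membrane, the pore wall
and the outer cylinder (those facets simply do not exist in the flux
graph).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import SpeciesSpec
from .constants import CONSTANTS, PhysicalConstants
from .mesh import LIQUID, Mesh
from .poisson import SolverError

_DELTA_CLIP = 500.0  # dimensionless drift numbers beyond this saturate


class StabilityError(RuntimeError):
    """Explicit transport step produced an unstable (negative) update."""


def bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), evaluated stably (B(0) = 1)."""
    x = np.clip(np.asarray(x, dtype=float), -_DELTA_CLIP, _DELTA_CLIP)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = x[nz] / np.expm1(x[nz])
    small = ~nz
    out[small] = 1.0 - 0.5 * x[small]
    return out


def edge_flux(
    c_up: float,
    c_down: float,
    dV: float,
    D: float,
    z: int,
    T: float,
    distance: float,
    area: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Scharfetter-Gummel molar flow (mol/s) from the 'up' to the 'down' cell.

    ``dV`` is V(down) - V(up).  Positive return value means net transport
    up -> down.  Exact for the two-point 1D drift-diffusion problem; zero
    when c_down/c_up equals the Boltzmann factor exp(-z e dV / k_B T).
    """
    if distance <= 0 or area <= 0:
        raise ValueError("facet distance and area must be positive")
    if not all(map(math.isfinite, (c_up, c_down, dV))):
        raise FloatingPointError("non-finite input to edge_flux")
    delta = z * constants.elementary_charge * dV / (constants.boltzmann * T)
    b = bernoulli(np.array([delta, -delta]))
    return float(D * area / distance * (c_up * b[0] - c_down * b[1]))


@dataclass
class TransportSystem:
    """Flux graph and transport operators for the liquid cells of a mesh.

    Parameters
    ----------
    mesh : Mesh
    species : tuple of SpeciesSpec
    temperature : K
    dirichlet_tags : boundary tags whose touching cell layer is pinned to the
        bulk concentration (empty tuple = fully closed domain).
    """

    mesh: Mesh
    species: tuple[SpeciesSpec, ...]
    temperature: float
    dirichlet_tags: tuple[str, ...] = ("left_end", "right_end")
    constants: PhysicalConstants = CONSTANTS

    def __post_init__(self) -> None:
        mesh = self.mesh
        if mesh.quads is None or mesh.quad_of_triangle is None:
            raise SolverError("transport needs a structured (quad-backed) mesh")
        # finite-volume cells are the structured quads: on the tensor mesh
        # their center connections are normal to the shared faces, which the
        # consistency of the two-point SG flux requires
        qregion = mesh.region[::2]
        self.cell_quads = np.nonzero(qregion == LIQUID)[0]
        self.n_cells = len(self.cell_quads)
        n_quads = len(mesh.quads)
        cell_of_quad = np.full(n_quads, -1, dtype=np.int64)
        cell_of_quad[self.cell_quads] = np.arange(self.n_cells)
        self.cell_of_quad = cell_of_quad
        self.cell_nodes = mesh.quads[self.cell_quads]  # (C, 4)
        tri_vol = mesh.volume
        self.volume = tri_vol[2 * self.cell_quads] + tri_vol[2 * self.cell_quads + 1]
        self.centroid = mesh.nodes[self.cell_nodes].mean(axis=1)  # corner mean

        # interior liquid-liquid faces = mesh edges between two distinct
        # liquid quads (the quad diagonals connect a quad to itself)
        et = mesh.edge_tri
        interior = et.min(axis=1) >= 0
        q0 = np.where(interior, mesh.quad_of_triangle[et[:, 0]], -1)
        q1 = np.where(interior, mesh.quad_of_triangle[et[:, 1]], -1)
        liq = (
            interior
            & (q0 != q1)
            & (mesh.region[et[:, 0]] == LIQUID)
            & (mesh.region[et[:, 1]] == LIQUID)
        )
        face_edges = np.nonzero(liq)[0]
        self.face_edges = face_edges
        self.face_cells = np.column_stack(
            [cell_of_quad[q0[face_edges]], cell_of_quad[q1[face_edges]]]
        )
        self.face_area = mesh.edge_revolved_area(face_edges)
        d = self.centroid[self.face_cells[:, 1]] - self.centroid[self.face_cells[:, 0]]
        self.face_dist = np.hypot(d[:, 0], d[:, 1])
        if np.any(self.face_dist <= 0):
            raise SolverError("coincident cell centers in flux graph")
        self.face_coeff = self.face_area / self.face_dist
        self.dx_min = float(self.face_dist.min())

        # Dirichlet (bulk-pinned) cell layer
        pinned = np.zeros(self.n_cells, dtype=bool)
        for tag in self.dirichlet_tags:
            for k in self.mesh.boundary_tags[tag]:
                t = et[k, 0]
                if t >= 0:
                    c = cell_of_quad[mesh.quad_of_triangle[t]]
                    if c >= 0:
                        pinned[c] = True
        self.pinned = pinned

        kT = self.constants.boltzmann * self.temperature
        self._e_over_kT = self.constants.elementary_charge / kT

        # constant COO pattern for the per-species transport operator
        f = self.face_cells
        self._rows = np.concatenate([f[:, 0], f[:, 0], f[:, 1], f[:, 1]])
        self._cols = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 0]])

    # ------------------------------------------------------------------
    def cell_voltage(self, V: np.ndarray) -> np.ndarray:
        """Nodal voltage averaged to the liquid cell centers."""
        return V[self.cell_nodes].mean(axis=1)

    def bulk_concentrations(self) -> list[np.ndarray]:
        """Uniform bulk fields, one per species."""
        return [np.full(self.n_cells, s.bulk_concentration) for s in self.species]

    def _face_deltas(self, V: np.ndarray) -> np.ndarray:
        """Dimensionless e dV / kT per face (cell0 -> cell1), before z scaling."""
        Vc = self.cell_voltage(V)
        return self._e_over_kT * (Vc[self.face_cells[:, 1]] - Vc[self.face_cells[:, 0]])

    def face_fluxes(self, V: np.ndarray, c: np.ndarray, species_idx: int) -> np.ndarray:
        """SG molar flow (mol/s) through each face, oriented cell0 -> cell1."""
        s = self.species[species_idx]
        delta = s.charge_number * self._face_deltas(V)
        k12 = s.diffusion_coefficient * self.face_coeff * bernoulli(delta)
        k21 = s.diffusion_coefficient * self.face_coeff * bernoulli(-delta)
        return k12 * c[self.face_cells[:, 0]] - k21 * c[self.face_cells[:, 1]]

    # ------------------------------------------------------------------
    def _operator(self, V: np.ndarray, species_idx: int) -> tuple[sp.csr_matrix, float]:
        """Sparse operator M with dc/dt = M c (pinned rows zeroed).

        Returns (M, max_rate): max_rate = max_i |M_ii| bounds the explicit
        step for positivity (off-diagonals of M are nonnegative).
        """
        s = self.species[species_idx]
        delta = s.charge_number * self._face_deltas(V)
        k12 = s.diffusion_coefficient * self.face_coeff * bernoulli(delta)
        k21 = s.diffusion_coefficient * self.face_coeff * bernoulli(-delta)
        v0 = self.volume[self.face_cells[:, 0]]
        v1 = self.volume[self.face_cells[:, 1]]
        data = np.concatenate([-k12 / v0, k21 / v0, -k21 / v1, k12 / v1])
        M = sp.coo_matrix(
            (data, (self._rows, self._cols)), shape=(self.n_cells, self.n_cells)
        ).tocsr()
        if self.pinned.any():
            keep = sp.diags((~self.pinned).astype(float))
            M = keep @ M
        diag = M.diagonal()
        max_rate = float(np.abs(diag).max()) if len(diag) else 0.0
        return M, max_rate

    def stability_dt(self, transport_step_fraction: float) -> float:
        """Diffusive explicit stability bound f_NP * dx_min^2 / D_max."""
        D_max = max(s.diffusion_coefficient for s in self.species)
        return transport_step_fraction * self.dx_min**2 / D_max

    def advance_block(
        self,
        concentrations: list[np.ndarray],
        V: np.ndarray,
        block_dt: float,
        transport_step_fraction: float,
    ) -> list[np.ndarray]:
        """Advance all species by ``block_dt`` with frozen voltage.

        The inner explicit step is the diffusive bound capped by the
        forward-Euler positivity limit of the assembled operator, so
        concentrations stay nonnegative by construction.
        """
        ops = [self._operator(V, i) for i in range(len(self.species))]
        dt = self.stability_dt(transport_step_fraction)
        max_rate = max(rate for _, rate in ops)
        if max_rate > 0:
            dt = min(dt, 0.95 / max_rate)
        n_inner = max(1, math.ceil(block_dt / dt))
        dt = block_dt / n_inner
        out = [c.copy() for c in concentrations]
        for _ in range(n_inner):
            for i, (M, _) in enumerate(ops):
                out[i] += dt * (M @ out[i])
        for i, c in enumerate(out):
            if np.any(c < -1e-9 * self.species[i].bulk_concentration):
                raise StabilityError(
                    f"negative concentration for species {self.species[i].name}: "
                    f"min {c.min():.3e} mol/m^3 (reduce the transport step)"
                )
            np.clip(c, 0.0, None, out=c)
        return out

    # ------------------------------------------------------------------
    def steady_solve(self, V: np.ndarray, species_idx: int) -> np.ndarray:
        """Frozen-field steady state of one species: div j = 0.

        Linear solve with SG edge coefficients, Dirichlet bulk values in the
        pinned layer, zero flux elsewhere.
        """
        if not self.pinned.any():
            raise SolverError("steady transport solve needs Dirichlet cells")
        M, _ = self._operator(V, species_idx)
        # pinned rows were zeroed in M; add an identity there
        A = M + sp.diags(self.pinned.astype(float))
        b = np.where(self.pinned, self.species[species_idx].bulk_concentration, 0.0)
        c = spla.spsolve(A.tocsc(), b)
        if not np.all(np.isfinite(c)):
            raise SolverError("steady transport solve produced non-finite values")
        return c

    # ------------------------------------------------------------------
    def charge_density(self, concentrations: list[np.ndarray]) -> np.ndarray:
        """Mobile space charge rho = F sum_i z_i c_i per mesh triangle (C/m^3).

        The per-cell value is carried by both triangle halves of each quad.
        """
        rho_cell = np.zeros(self.n_cells)
        for s, c in zip(self.species, concentrations):
            rho_cell += self.constants.faraday * s.charge_number * c
        rho = np.zeros(self.mesh.n_triangles)
        rho[2 * self.cell_quads] = rho_cell
        rho[2 * self.cell_quads + 1] = rho_cell
        return rho

    def total_moles(self, c: np.ndarray) -> float:
        """Axisymmetric volume integral of one concentration field (mol)."""
        return float(np.sum(c * self.volume))
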