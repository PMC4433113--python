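"""Axisymmetric Poisson solver with piecewise-linear finite elements.

Solves div(eps grad V) = -F sum_i z_i c_i on the full domain -- liquid AND
membrane -- in cylindrical coordinates (all weak-form integrals carry the
2 pi r weight).  Fixed surface charges at the water/nitride interface enter
as natural interface source terms; no Neumann wall condition
V_perp = sigma_S/eps is imposed, so ions outside the pore can take part in
screening the pore-wall charge.  Dirichlet voltages hold at the reservoir
far ends; the outer cylinder carries zero normal displacement (natural);
the axis r = 0 needs no condition (the 2 pi r weight vanishes there).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import LIQUID, Mesh, SurfaceChargeMap


class SolverError(RuntimeError):
    """Singular system or failed linear solve."""


def triangle_gradients(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Constant P1 basis gradients per triangle.

    Returns (grad_r, grad_z), each (M, 3): gradient components of the three
    nodal hat functions on each triangle.
    """
    pts = mesh.nodes
    t = mesh.triangles
    x = pts[t, 0]  # (M, 3) radii
    y = pts[t, 1]  # (M, 3) z
    A2 = 2 * mesh.area
    # grad phi_a = (y_b - y_c, x_c - x_b) / (2A), cyclic
    gr = np.empty_like(x)
    gz = np.empty_like(x)
    for a in range(3):
        b, c = (a + 1) % 3, (a + 2) % 3
        gr[:, a] = (y[:, b] - y[:, c]) / A2
        gz[:, a] = (x[:, c] - x[:, b]) / A2
    return gr, gz


@dataclass
class PoissonSolver:
    """Pre-assembled, pre-factorized Poisson operator for one mesh.

    The stiffness matrix depends only on mesh and permittivity, so it is
    assembled and LU-factorized once; each solve only rebuilds the load
    vector (mobile charge + surface charge) and back-substitutes.

    Parameters
    ----------
    mesh : Mesh
    permittivity : (M,) array
        Absolute permittivity eps0*epsr per triangle, F/m.
    """

    mesh: Mesh
    permittivity: np.ndarray

    def __post_init__(self) -> None:
        mesh = self.mesh
        eps = np.asarray(self.permittivity, dtype=float)
        if eps.shape != (mesh.n_triangles,) or np.any(eps <= 0):
            raise SolverError("permittivity must be positive, one value per triangle")
        gr, gz = triangle_gradients(mesh)
        self._grad = (gr, gz)
        w = 2 * math.pi * mesh.centroid[:, 0] * mesh.area * eps  # eps * 2 pi r_bar A
        n = mesh.n_nodes
        rows, cols, vals = [], [], []
        t = mesh.triangles
        for a in range(3):
            for b in range(3):
                rows.append(t[:, a])
                cols.append(t[:, b])
                vals.append(w * (gr[:, a] * gr[:, b] + gz[:, a] * gz[:, b]))
        K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()

        left = mesh.boundary_nodes("left_end")
        right = mesh.boundary_nodes("right_end")
        if len(left) == 0 and len(right) == 0:
            raise SolverError("no Dirichlet nodes: Poisson system is singular")
        self._left, self._right = left, right
        dirichlet = np.concatenate([left, right])
        free = np.setdiff1d(np.arange(n), dirichlet)
        self._free, self._dirichlet = free, dirichlet
        self._K_ff = K[np.ix_(free, free)].tocsc()
        self._K_fd = K[np.ix_(free, dirichlet)].tocsr()
        try:
            self._lu = spla.splu(self._K_ff)
        except RuntimeError as exc:  # pragma: no cover
            raise SolverError(f"Poisson factorization failed: {exc}") from exc

        # precomputed load-vector geometry:
        # volume source: integral of phi_a * r over triangle = A (2 r_a + r_b + r_c)/12
        r_nodes = mesh.nodes[t, 0]
        self._vol_w = (
            2
            * math.pi
            * mesh.area[:, None]
            * (r_nodes + r_nodes.sum(axis=1, keepdims=True))
            / 12.0
        )  # (M, 3), multiply by per-triangle rho and scatter to t

    def solve(
        self,
        charge_density: np.ndarray,
        charges: SurfaceChargeMap | None,
        V_left: float,
        V_right: float,
    ) -> np.ndarray:
        """Nodal voltage solution.

        Parameters
        ----------
        charge_density : (M,) array
            Mobile space charge rho = F sum_i z_i c_i per triangle, C/m^3
            (zero on membrane triangles).
        charges : SurfaceChargeMap or None
            Fixed interface charge, entering as int sigma w 2 pi r ds.
        """
        mesh = self.mesh
        rho = np.asarray(charge_density, dtype=float)
        b = np.zeros(mesh.n_nodes)
        np.add.at(b, mesh.triangles, self._vol_w * rho[:, None])
        if charges is not None:
            ie = mesh.interface_edges
            n = mesh.edges[ie]
            r0 = mesh.nodes[n[:, 0], 0]
            r1 = mesh.nodes[n[:, 1], 0]
            L = mesh.edge_length[ie]
            s = charges.sigma
            c0 = 2 * math.pi * s * L * (2 * r0 + r1) / 6.0
            c1 = 2 * math.pi * s * L * (r0 + 2 * r1) / 6.0
            np.add.at(b, n[:, 0], c0)
            np.add.at(b, n[:, 1], c1)

        V = np.empty(mesh.n_nodes)
        V[self._left] = V_left
        V[self._right] = V_right
        rhs = b[self._free] - self._K_fd @ V[self._dirichlet]
        V[self._free] = self._lu.solve(rhs)
        if not np.all(np.isfinite(V)):
            raise SolverError("Poisson solve produced non-finite voltages")
        return V

    def field_per_triangle(self, V: np.ndarray) -> np.ndarray:
        """Electric field E = -grad V, (M, 2) array (E_r, E_z), V/m."""
        gr, gz = self._grad
        Vt = V[self.mesh.triangles]
        return -np.stack([(Vt * gr).sum(axis=1), (Vt * gz).sum(axis=1)], axis=1)


def permittivity_field(mesh: Mesh, epsr_water: float, epsr_membrane: float,
                       eps0: float = 8.8541878128e-12) -> np.ndarray:
    """Per-triangle absolute permittivity from the region labels."""
    return np.where(mesh.region == LIQUID, epsr_water, epsr_membrane) * eps0


def interface_normal_fields(
    V: np.ndarray, mesh: Mesh, solver: PoissonSolver
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sided normal E components on both sides of each interface edge.

    Returns (E_perp_liquid, E_perp_membrane, normals); normals are unit
    vectors oriented liquid -> membrane, one row per interface edge.
    """
    mesh_ = mesh
    E = solver.field_per_triangle(V)
    ie = mesh_.interface_edges
    tri_pair = mesh_.edge_tri[ie]
    reg = mesh_.region
    liq = np.where(reg[tri_pair[:, 0]] == LIQUID, tri_pair[:, 0], tri_pair[:, 1])
    mem = np.where(reg[tri_pair[:, 0]] == LIQUID, tri_pair[:, 1], tri_pair[:, 0])
    n = mesh_.edges[ie]
    d = mesh_.nodes[n[:, 1]] - mesh_.nodes[n[:, 0]]
    L = np.hypot(d[:, 0], d[:, 1])
    normal = np.column_stack([d[:, 1], -d[:, 0]]) / L[:, None]
    mid = 0.5 * (mesh_.nodes[n[:, 0]] + mesh_.nodes[n[:, 1]])
    toward_mem = mesh_.centroid[mem] - mid
    flip = (normal * toward_mem).sum(axis=1) < 0
    normal[flip] *= -1
    E_liq = (E[liq] * normal).sum(axis=1)
    E_mem = (E[mem] * normal).sum(axis=1)
    return E_liq, E_mem, normal
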