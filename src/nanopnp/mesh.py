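"""Axisymmetric (r, z) domain construction and graded conforming triangulation.

The domain is a cylinder of radius ``domain_radius``: two electrolyte
reservoirs separated by a dielectric membrane pierced by a cylindrical or
conical pore.  The mesh is a mapped structured grid split into triangles:
one radial grid line follows the pore-wall line r = w(z), so the
liquid/membrane interface (pore wall and both membrane faces) lies exactly
on mesh edges.  Elements are graded: finest (``min_element_size``) at the
pore wall and membrane faces where double layers form, coarsening
geometrically toward the far boundaries.

Region labels: 0 = liquid, 1 = membrane.  Boundary tags: ``left_end``,
``right_end`` (reservoir far ends, Dirichlet planes), ``outer_cylinder``
(zero normal field / zero flux) and ``axis`` (r = 0, natural regularity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .config import GeometrySpec, NumericalControls, ValidationError

LIQUID = 0
MEMBRANE = 1

# interface-edge kinds
WALL = "pore_wall"
LEFT_FACE = "left_face"
RIGHT_FACE = "right_face"


@dataclass
class Mesh:
    """Tagged axisymmetric triangulation.

    Attributes
    ----------
    nodes : (N, 2) float array
        (r, z) coordinates in metres.
    triangles : (M, 3) int array
        CCW node indices.
    region : (M,) int array
        LIQUID or MEMBRANE per triangle.
    membrane_z : (float, float) or None
        Axial extent of the membrane, None for fixtures without one.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    region: np.ndarray
    membrane_z: tuple[float, float] | None = None
    #: (Q, 4) corner node indices of the structured quads (n00, n10, n11, n01)
    quads: np.ndarray | None = None
    #: (M,) parent quad index per triangle
    quad_of_triangle: np.ndarray | None = None

    # derived, filled by _finalize
    area: np.ndarray = field(init=False)
    centroid: np.ndarray = field(init=False)
    volume: np.ndarray = field(init=False)           # 2 pi r_bar * area
    edges: np.ndarray = field(init=False)            # (E, 2) node pairs
    edge_tri: np.ndarray = field(init=False)         # (E, 2) triangles, -1 = none
    edge_length: np.ndarray = field(init=False)
    boundary_tags: dict = field(init=False)          # tag -> edge index array
    interface_edges: np.ndarray = field(init=False)  # edges between liquid & membrane
    interface_kind: list = field(init=False)         # WALL / LEFT_FACE / RIGHT_FACE

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.region = np.asarray(self.region, dtype=np.int64)
        if np.any(self.nodes[:, 0] < -1e-18):
            raise ValidationError("mesh has nodes at negative radius")
        self._finalize()

    # ------------------------------------------------------------------
    def _finalize(self) -> None:
        pts = self.nodes
        tri = self.triangles
        p0, p1, p2 = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
        cross = (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1]) - (
            p1[:, 1] - p0[:, 1]
        ) * (p2[:, 0] - p0[:, 0])
        # enforce CCW orientation
        flip = cross < 0
        if np.any(flip):
            tri[flip, 1], tri[flip, 2] = tri[flip, 2].copy(), tri[flip, 1].copy()
            self.triangles = tri
            p1, p2 = pts[tri[:, 1]], pts[tri[:, 2]]
            cross = np.abs(cross)
        self.area = 0.5 * cross
        if np.any(self.area <= 0):
            raise ValidationError("degenerate (zero-area) triangle in mesh")
        self.centroid = (p0 + p1 + p2) / 3.0
        # exact volume of revolution of a linear-r triangle: 2 pi r_bar A
        self.volume = 2 * math.pi * self.centroid[:, 0] * self.area

        # edge table
        e = np.vstack(
            [tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]
        )
        e.sort(axis=1)
        owners = np.tile(np.arange(len(tri)), 3)
        edges, inv = np.unique(e, axis=0, return_inverse=True)
        edge_tri = np.full((len(edges), 2), -1, dtype=np.int64)
        for k, t in zip(inv, owners):
            if edge_tri[k, 0] < 0:
                edge_tri[k, 0] = t
            else:
                edge_tri[k, 1] = t
        self.edges = edges
        self.edge_tri = edge_tri
        d = pts[edges[:, 1]] - pts[edges[:, 0]]
        self.edge_length = np.hypot(d[:, 0], d[:, 1])

        # boundary tags
        r = pts[:, 0]
        z = pts[:, 1]
        rmax, zmin, zmax = r.max(), z.min(), z.max()
        tol_r = 1e-9 * max(rmax, 1e-12)
        tol_z = 1e-9 * max(zmax - zmin, 1e-12)
        is_boundary = edge_tri[:, 1] < 0
        n0, n1 = edges[:, 0], edges[:, 1]
        self.boundary_tags = {}
        for tag, mask in (
            ("left_end", (np.abs(z[n0] - zmin) < tol_z) & (np.abs(z[n1] - zmin) < tol_z)),
            ("right_end", (np.abs(z[n0] - zmax) < tol_z) & (np.abs(z[n1] - zmax) < tol_z)),
            ("outer_cylinder", (np.abs(r[n0] - rmax) < tol_r) & (np.abs(r[n1] - rmax) < tol_r)),
            ("axis", (np.abs(r[n0]) < tol_r) & (np.abs(r[n1]) < tol_r)),
        ):
            self.boundary_tags[tag] = np.nonzero(is_boundary & mask)[0]

        # liquid/membrane interface
        both = edge_tri.min(axis=1) >= 0
        reg = self.region
        iface = both & (reg[edge_tri[:, 0]] != reg[edge_tri[:, 1]])
        self.interface_edges = np.nonzero(iface)[0]
        self.interface_kind = []
        if self.membrane_z is not None:
            z0, z1 = self.membrane_z
            for k in self.interface_edges:
                za, zb = z[edges[k, 0]], z[edges[k, 1]]
                if abs(za - z0) < tol_z and abs(zb - z0) < tol_z:
                    self.interface_kind.append(LEFT_FACE)
                elif abs(za - z1) < tol_z and abs(zb - z1) < tol_z:
                    self.interface_kind.append(RIGHT_FACE)
                else:
                    self.interface_kind.append(WALL)
        else:
            self.interface_kind = [WALL] * len(self.interface_edges)

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def liquid_triangles(self) -> np.ndarray:
        return np.nonzero(self.region == LIQUID)[0]

    def edge_revolved_area(self, edge_indices: np.ndarray) -> np.ndarray:
        """Area of the surface of revolution of edges: 2 pi r_mid * length."""
        n = self.edges[edge_indices]
        r_mid = 0.5 * (self.nodes[n[:, 0], 0] + self.nodes[n[:, 1], 0])
        return 2 * math.pi * r_mid * self.edge_length[edge_indices]

    def triangle_quality(self) -> np.ndarray:
        """Per-triangle inradius/circumradius ratio (1/2 = equilateral ... 0)."""
        pts = self.nodes
        t = self.triangles
        a = np.linalg.norm(pts[t[:, 1]] - pts[t[:, 0]], axis=1)
        b = np.linalg.norm(pts[t[:, 2]] - pts[t[:, 1]], axis=1)
        c = np.linalg.norm(pts[t[:, 0]] - pts[t[:, 2]], axis=1)
        s = 0.5 * (a + b + c)
        inr = self.area / s
        circ = a * b * c / (4 * self.area)
        return inr / circ

    def boundary_nodes(self, tag: str) -> np.ndarray:
        return np.unique(self.edges[self.boundary_tags[tag]].ravel())


@dataclass
class SurfaceChargeMap:
    """Fixed surface charge density per interface edge (C/m^2).

    ``sigma`` holds one value per entry of ``mesh.interface_edges``;
    unlisted (zero) edges simply carry 0.
    """

    mesh: Mesh
    sigma: np.ndarray  # aligned with mesh.interface_edges

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (len(self.mesh.interface_edges),):
            raise ValidationError("charge map length must match interface edge count")

    def total_charge(self) -> float:
        """Integral of sigma over the revolved interface surface, in C."""
        areas = self.mesh.edge_revolved_area(self.mesh.interface_edges)
        return float(np.sum(self.sigma * areas))


def make_charge_map(mesh: Mesh, configuration: str, sigma_S: float) -> SurfaceChargeMap:
    """Assign the fixed surface charge for one of the named configurations.

    - ``uncharged``:    no charged edges
    - ``a_uniform``:    pore wall + both membrane faces at sigma_S
    - ``b_pore_only``:  pore wall only
    - ``c_asymmetric``: left membrane face + left half of the pore wall
    - ``custom``:       returns an all-zero map for the caller to fill in
    """
    if len(mesh.interface_edges) == 0:
        raise ValidationError("mesh has no liquid/membrane interface edges")
    kinds = mesh.interface_kind
    sig = np.zeros(len(mesh.interface_edges))
    if configuration in ("uncharged", "custom"):
        pass
    elif configuration == "a_uniform":
        sig[:] = sigma_S
    elif configuration == "b_pore_only":
        sig[[k == WALL for k in kinds]] = sigma_S
    elif configuration == "c_asymmetric":
        if mesh.membrane_z is None:
            raise ValidationError("asymmetric configuration requires a membrane")
        z_mid = 0.5 * sum(mesh.membrane_z)
        mid_z = 0.5 * (
            mesh.nodes[mesh.edges[mesh.interface_edges, 0], 1]
            + mesh.nodes[mesh.edges[mesh.interface_edges, 1], 1]
        )
        pick = np.array(
            [
                kind == LEFT_FACE or (kind == WALL and zm < z_mid + 1e-15)
                for kind, zm in zip(kinds, mid_z)
            ]
        )
        sig[pick] = sigma_S
    else:
        raise ValidationError(
            f"unknown charge configuration {configuration!r}; valid: "
            "uncharged, a_uniform, b_pore_only, c_asymmetric, custom"
        )
    return SurfaceChargeMap(mesh=mesh, sigma=sig)


# ---------------------------------------------------------------------------
# graded 1D point distributions
# ---------------------------------------------------------------------------

def graded_segment(
    length: float,
    h_start: float,
    h_end: float,
    ratio: float,
    h_max: float = math.inf,
) -> np.ndarray:
    """Points on [0, length] with geometric grading from both ends.

    Cell sizes start at ``h_start`` / ``h_end`` at the two ends and grow by
    ``ratio`` toward the middle, capped at ``h_max``; sizes are then scaled
    down uniformly so the cells exactly tile the segment.
    """
    if length <= 0:
        raise ValidationError("segment length must be positive")
    if ratio <= 1:
        raise ValidationError(f"mesh growth ratio must exceed 1, got {ratio}")
    sizes_a: list[float] = []
    sizes_b: list[float] = []
    ha, hb = h_start, h_end
    total = 0.0
    while total < length:
        if ha <= hb:
            sizes_a.append(min(ha, h_max))
            total += sizes_a[-1]
            ha = min(ha * ratio, h_max)
        else:
            sizes_b.append(min(hb, h_max))
            total += sizes_b[-1]
            hb = min(hb * ratio, h_max)
    sizes = np.array(sizes_a + sizes_b[::-1])
    sizes *= length / sizes.sum()
    pts = np.concatenate([[0.0], np.cumsum(sizes)])
    pts[-1] = length  # exact endpoint despite fp rounding
    return pts


# ---------------------------------------------------------------------------
# generic tensor-product mesh builder
# ---------------------------------------------------------------------------

def tensor_mesh(
    r_grid: np.ndarray,
    z_lines: np.ndarray,
    region_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    membrane_z: tuple[float, float] | None,
) -> Mesh:
    """Build a triangle mesh from per-z-line radial node positions.

    ``r_grid`` has shape (n_z, n_r): radial coordinates of the grid nodes on
    each axial line (they may differ between lines, e.g. to follow a conical
    pore wall).  Each quad is split along a fixed diagonal.
    ``region_fn(r, z)`` maps centroid coordinates to region labels.
    """
    n_z, n_r = r_grid.shape
    if len(z_lines) != n_z:
        raise ValidationError("z_lines length must match r_grid rows")
    zz = np.repeat(z_lines, n_r)
    rr = r_grid.ravel()
    nodes = np.column_stack([rr, zz])

    def nid(j: int, i: int) -> int:
        return j * n_r + i

    tris = []
    quads = []
    for j in range(n_z - 1):
        for i in range(n_r - 1):
            n00 = nid(j, i)
            n10 = nid(j, i + 1)
            n01 = nid(j + 1, i)
            n11 = nid(j + 1, i + 1)
            quads.append((n00, n10, n11, n01))
            tris.append((n00, n10, n11))
            tris.append((n00, n11, n01))
    triangles = np.array(tris, dtype=np.int64)
    quads_arr = np.array(quads, dtype=np.int64)
    quad_of_triangle = np.repeat(np.arange(len(quads_arr)), 2)
    # classify regions per quad (its corner mean) so both halves agree
    qcen_r = nodes[quads_arr, 0].mean(axis=1)
    qcen_z = nodes[quads_arr, 1].mean(axis=1)
    qregion = region_fn(qcen_r, qcen_z).astype(np.int64)
    region = qregion[quad_of_triangle]
    return Mesh(
        nodes=nodes,
        triangles=triangles,
        region=region,
        membrane_z=membrane_z,
        quads=quads_arr,
        quad_of_triangle=quad_of_triangle,
    )


# ---------------------------------------------------------------------------
# domain meshes
# ---------------------------------------------------------------------------

def build_mesh(spec: GeometrySpec, controls: NumericalControls) -> Mesh:
    """Mesh the two-reservoir + membrane/pore domain.

    Finest elements (``controls.min_element_size``) sit along the pore wall
    and the membrane faces; element size grows by ``controls.mesh_growth_ratio``
    toward the reservoir ends and the outer cylinder.
    """
    h0 = controls.min_element_size
    g = controls.mesh_growth_ratio
    L_m = spec.membrane_thickness
    L_res = spec.reservoir_depth
    R = spec.domain_radius
    h_cap = max(R, L_res) / 6.0

    # axial lines: reservoir | membrane | reservoir, fine at both faces
    z_left = graded_segment(L_res, h_cap, h0, g, h_max=h_cap) - L_res
    z_mem = graded_segment(L_m, h0, h0, g, h_max=h_cap)
    z_right = graded_segment(L_res, h0, h_cap, g, h_max=h_cap) + L_m
    z_lines = np.unique(np.concatenate([z_left, z_mem, z_right + 0.0]))

    # radial template fractions: inner block [0, w], outer block [w, R]
    r_small = spec.pore_diameter_small / 2
    inner = graded_segment(r_small, 2 * h0, h0, g, h_max=h_cap)
    frac_inner = inner / r_small
    outer = graded_segment(R - r_small, h0, h_cap, g, h_max=h_cap)
    frac_outer = outer / (R - r_small)

    def wall(z: float) -> float:
        zc = min(max(z, 0.0), L_m)
        return spec.wall_radius(zc)

    r_grid = np.empty((len(z_lines), len(frac_inner) + len(frac_outer) - 1))
    for j, z in enumerate(z_lines):
        w = wall(z)
        r_grid[j, : len(frac_inner)] = frac_inner * w
        r_grid[j, len(frac_inner):] = w + frac_outer[1:] * (R - w)

    def region_fn(r: np.ndarray, z: np.ndarray) -> np.ndarray:
        w = np.array([wall(zi) for zi in z])
        return ((z > 0) & (z < L_m) & (r > w)).astype(np.int64)

    return tensor_mesh(r_grid, z_lines, region_fn, membrane_z=(0.0, L_m))


def build_column_mesh(radius: float, length: float, n_r: int, n_z: int) -> Mesh:
    """Uniform all-liquid cylinder fixture (no membrane): 1D closed forms apply."""
    r_pts = np.linspace(0.0, radius, n_r)
    z_pts = np.linspace(0.0, length, n_z)
    r_grid = np.tile(r_pts, (n_z, 1))
    return tensor_mesh(
        r_grid, z_pts, lambda r, z: np.zeros_like(r, dtype=np.int64), membrane_z=None
    )


def build_plate_mesh(
    radius: float,
    water_depth: float,
    membrane_thickness: float,
    h_z: float,
    n_r: int = 4,
    ratio: float = 1.3,
) -> Mesh:
    """Pore-less membrane slab spanning the full radius (capacitor fixture).

    Liquid occupies z in [-water_depth, 0] and [L_m, L_m + water_depth];
    the membrane spans [0, L_m] at all radii.  The axial grading is fine
    (``h_z``) at both membrane faces.
    """
    L_m = membrane_thickness
    z_left = graded_segment(water_depth, water_depth / 3, h_z, ratio) - water_depth
    z_mem = graded_segment(L_m, h_z, h_z, ratio)
    z_right = graded_segment(water_depth, h_z, water_depth / 3, ratio) + L_m
    z_lines = np.unique(np.concatenate([z_left, z_mem, z_right]))
    r_pts = np.linspace(0.0, radius, n_r)
    r_grid = np.tile(r_pts, (len(z_lines), 1))

    def region_fn(r: np.ndarray, z: np.ndarray) -> np.ndarray:
        return ((z > 0) & (z < L_m)).astype(np.int64)

    return tensor_mesh(r_grid, z_lines, region_fn, membrane_z=(0.0, L_m))
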