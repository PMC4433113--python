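import math

import numpy as np
import pytest

from nanopnp.config import GeometrySpec, NumericalControls, ValidationError
from nanopnp.constants import NM
from nanopnp.mesh import (
    LIQUID,
    MEMBRANE,
    WALL,
    LEFT_FACE,
    RIGHT_FACE,
    build_column_mesh,
    build_mesh,
    build_plate_mesh,
    graded_segment,
    make_charge_map,
)


@pytest.fixture(scope="module")
def controls():
    return NumericalControls(min_element_size=1.0 * NM, mesh_growth_ratio=1.45)


@pytest.fixture(scope="module")
def cyl_mesh(controls):
    return build_mesh(GeometrySpec(), controls)


@pytest.fixture(scope="module")
def cone_mesh(controls):
    return build_mesh(GeometrySpec(opening_angle=20.0, large_opening_side="right"), controls)


class TestGradedSegment:
    def test_endpoints_and_monotonicity(self):
        pts = graded_segment(100 * NM, 1 * NM, 5 * NM, 1.3)
        assert pts[0] == 0.0 and pts[-1] == 100 * NM
        assert np.all(np.diff(pts) > 0)

    def test_min_size_not_exceeded_at_fine_end(self):
        pts = graded_segment(100 * NM, 1 * NM, 5 * NM, 1.3)
        assert np.diff(pts)[0] <= 1 * NM * (1 + 1e-9)

    def test_growth_ratio_must_exceed_one(self):
        with pytest.raises(ValidationError):
            graded_segment(1.0, 0.1, 0.1, 1.0)


class TestDomainMesh:
    def test_triangle_areas_tile_the_domain(self, cyl_mesh):
        g = GeometrySpec()
        analytic = g.domain_radius * (2 * g.reservoir_depth + g.membrane_thickness)
        assert cyl_mesh.area.sum() == pytest.approx(analytic, rel=1e-10)

    def test_conforming_no_orphan_interior_edges(self, cyl_mesh):
        # every edge has one or two adjacent triangles; every interface edge
        # separates exactly one liquid and one membrane triangle
        assert np.all(cyl_mesh.edge_tri[:, 0] >= 0)
        for k in cyl_mesh.interface_edges:
            t0, t1 = cyl_mesh.edge_tri[k]
            assert {cyl_mesh.region[t0], cyl_mesh.region[t1]} == {LIQUID, MEMBRANE}

    def test_all_radii_nonnegative(self, cyl_mesh):
        assert cyl_mesh.nodes[:, 0].min() >= 0.0

    def test_boundary_tags_cover_the_hull(self, cyl_mesh):
        n_boundary = int((cyl_mesh.edge_tri[:, 1] < 0).sum())
        tagged = sum(len(v) for v in cyl_mesh.boundary_tags.values())
        assert tagged == n_boundary

    def test_pore_wall_edges_at_5nm_for_cylinder(self, cyl_mesh):
        wall = [k for k, kind in zip(cyl_mesh.interface_edges, cyl_mesh.interface_kind)
                if kind == WALL]
        r = cyl_mesh.nodes[cyl_mesh.edges[wall].ravel(), 0]
        assert np.allclose(r, 5 * NM, rtol=1e-12)

    def test_cone_wall_follows_line(self, cone_mesh):
        tan = math.tan(math.radians(10.0))
        wall = [k for k, kind in zip(cone_mesh.interface_edges, cone_mesh.interface_kind)
                if kind == WALL]
        nodes = np.unique(cone_mesh.edges[wall].ravel())
        r, z = cone_mesh.nodes[nodes, 0], cone_mesh.nodes[nodes, 1]
        assert np.allclose(r, 5 * NM + z * tan, rtol=1e-9)

    def test_axisymmetric_volume_weight(self, cyl_mesh):
        # total revolved volume = pi R^2 H
        g = GeometrySpec()
        vol = math.pi * g.domain_radius**2 * (2 * g.reservoir_depth + g.membrane_thickness)
        assert cyl_mesh.volume.sum() == pytest.approx(vol, rel=1e-10)

    def test_triangle_quality_floor(self, cyl_mesh):
        # graded anisotropic mesh: sliver floor documented at 5e-3
        assert cyl_mesh.triangle_quality().min() > 5e-3

    def test_refinement_has_subnanometer_wall_cells(self, controls):
        fine = NumericalControls(min_element_size=0.5 * NM, mesh_growth_ratio=1.3)
        m = build_mesh(GeometrySpec(), fine)
        assert m.n_triangles > build_mesh(GeometrySpec(), controls).n_triangles


class TestChargeMaps:
    def test_uniform_configuration_charges_every_interface_edge(self, cyl_mesh):
        cm = make_charge_map(cyl_mesh, "a_uniform", -0.05)
        assert np.all(cm.sigma == -0.05)

    def test_uncharged_map_is_empty(self, cyl_mesh):
        cm = make_charge_map(cyl_mesh, "uncharged", -0.05)
        assert np.all(cm.sigma == 0.0)

    def test_uniform_total_charge_matches_surface_integral(self, cyl_mesh):
        cm = make_charge_map(cyl_mesh, "a_uniform", -0.05)
        r, R, L = 5 * NM, 250 * NM, 20 * NM
        area = 2 * math.pi * r * L + 2 * math.pi * (R**2 - r**2)
        assert cm.total_charge() == pytest.approx(-0.05 * area, rel=1e-8)

    def test_pore_only_charges_wall_arc_length_only(self, cyl_mesh):
        cm = make_charge_map(cyl_mesh, "b_pore_only", -0.05)
        charged = cm.sigma != 0
        kinds = np.array(cyl_mesh.interface_kind)
        assert np.all(kinds[charged] == WALL)
        L = cyl_mesh.edge_length[cyl_mesh.interface_edges[charged]].sum()
        assert L == pytest.approx(20 * NM, rel=1e-9)

    def test_cone_wall_charge_matches_frustum_area(self, cone_mesh):
        cm = make_charge_map(cone_mesh, "b_pore_only", -0.05)
        g = GeometrySpec(opening_angle=20.0)
        r1, r2 = 5 * NM, g.large_diameter / 2
        slant = math.hypot(r2 - r1, 20 * NM)
        frustum = math.pi * (r1 + r2) * slant
        assert cm.total_charge() == pytest.approx(-0.05 * frustum, rel=1e-8)

    def test_asymmetric_charges_left_face_and_left_half_wall(self, cyl_mesh):
        cm = make_charge_map(cyl_mesh, "c_asymmetric", -0.05)
        kinds = np.array(cyl_mesh.interface_kind)
        charged = cm.sigma != 0
        assert np.all(kinds[charged] != RIGHT_FACE)
        assert np.any(kinds[charged] == LEFT_FACE)
        wall_charged = cyl_mesh.interface_edges[charged & (kinds == WALL)]
        z_mid = cyl_mesh.nodes[cyl_mesh.edges[wall_charged].ravel(), 1]
        assert z_mid.max() <= 10 * NM + 1e-15

    def test_unknown_configuration_rejected(self, cyl_mesh):
        with pytest.raises(ValidationError):
            make_charge_map(cyl_mesh, "nonsense", -0.05)


class TestFixtures:
    def test_column_mesh_is_all_liquid(self):
        m = build_column_mesh(50 * NM, 100 * NM, 5, 11)
        assert np.all(m.region == LIQUID)
        assert len(m.interface_edges) == 0

    def test_plate_mesh_slab_spans_radius(self):
        m = build_plate_mesh(50 * NM, 50 * NM, 20 * NM, 2 * NM)
        kinds = set(m.interface_kind)
        assert kinds == {LEFT_FACE, RIGHT_FACE}
        # membrane volume = pi R^2 L_m
        vol_mem = m.volume[m.region == MEMBRANE].sum()
        assert vol_mem == pytest.approx(math.pi * (50 * NM) ** 2 * 20 * NM, rel=1e-10)
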