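import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanopnp.config import kcl_electrolyte
from nanopnp.constants import NM, thermal_voltage
from nanopnp.mesh import build_column_mesh
from nanopnp.observables import plane_currents
from nanopnp.transport import TransportSystem, bernoulli, edge_flux

T = 298.15


@pytest.fixture(scope="module")
def column_system():
    mesh = build_column_mesh(20 * NM, 100 * NM, 5, 41)
    return TransportSystem(mesh, kcl_electrolyte(10.0).species, T)


@pytest.fixture(scope="module")
def closed_system():
    mesh = build_column_mesh(20 * NM, 100 * NM, 5, 41)
    return TransportSystem(mesh, kcl_electrolyte(10.0).species, T, dirichlet_tags=())


class TestScharfetterGummel:
    def test_equilibrium_no_gradient_no_flux(self):
        assert edge_flux(10.0, 10.0, 0.0, 2e-9, 1, T, 1 * NM, 1e-18) == 0.0

    def test_drift_free_limit_is_fick(self):
        q = edge_flux(10.0, 5.0, 0.0, 2e-9, 1, T, 1 * NM, 1e-18)
        assert q == pytest.approx(2e-9 * 1e-18 / (1 * NM) * 5.0, rel=1e-12)

    @given(
        dV=st.floats(-0.3, 0.3),
        c_up=st.floats(0.1, 1000.0),
        z=st.sampled_from([-1, 1]),
    )
    @settings(max_examples=200, deadline=None)
    def test_boltzmann_ratio_kills_flux(self, dV, c_up, z):
        # SG is exact at thermal equilibrium: c_down/c_up = exp(-z e dV / kT)
        c_down = c_up * math.exp(-z * dV / thermal_voltage(T))
        q = edge_flux(c_up, c_down, dV, 2e-9, z, T, 1 * NM, 1e-18)
        scale = 2e-9 * 1e-18 / (1 * NM) * max(c_up, c_down)
        assert abs(q) <= 1e-12 * scale

    @given(dV=st.floats(-0.5, 0.5), c1=st.floats(0.0, 100.0), c2=st.floats(0.0, 100.0))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_under_orientation_flip(self, dV, c1, c2):
        q_fwd = edge_flux(c1, c2, dV, 2e-9, 1, T, 1 * NM, 1e-18)
        q_rev = edge_flux(c2, c1, -dV, 2e-9, 1, T, 1 * NM, 1e-18)
        assert q_fwd == pytest.approx(-q_rev, rel=1e-12, abs=1e-30)

    def test_species_symmetry_z_and_V_flip(self):
        # (z -> -z, V -> -V) maps cation onto anion transport
        q_K = edge_flux(8.0, 12.0, 0.04, 1.95e-9, 1, T, 1 * NM, 1e-18)
        q_Cl = edge_flux(8.0, 12.0, -0.04, 1.95e-9, -1, T, 1 * NM, 1e-18)
        assert q_K == pytest.approx(q_Cl, rel=1e-12)

    def test_bernoulli_stable_at_extremes(self):
        x = np.array([-1e4, -700.0, -1e-14, 0.0, 1e-14, 700.0, 1e4])
        b = bernoulli(x)
        assert np.all(np.isfinite(b))
        assert b[3] == 1.0
        assert bernoulli(np.array([1e-8]))[0] == pytest.approx(1.0, abs=1e-7)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(FloatingPointError):
            edge_flux(float("nan"), 1.0, 0.0, 2e-9, 1, T, 1 * NM, 1e-18)


class TestExplicitUpdate:
    def test_uniform_bulk_is_fixed_point(self, column_system):
        ts = column_system
        V = np.zeros(ts.mesh.n_nodes)
        c = ts.bulk_concentrations()
        out = ts.advance_block(c, V, 1e-9, 0.2)
        for o in out:
            assert np.abs(o - 10.0).max() < 1e-12

    def test_closed_domain_conserves_moles(self, closed_system):
        ts = closed_system
        V = np.zeros(ts.mesh.n_nodes)
        c0 = 10.0 * (1 + 0.5 * np.sin(ts.centroid[:, 1] / (10 * NM)))
        before = ts.total_moles(c0)
        out = ts.advance_block([c0, np.full(ts.n_cells, 10.0)], V, 1e-9, 0.2)
        assert ts.total_moles(out[0]) == pytest.approx(before, rel=1e-12)

    def test_concentrations_stay_nonnegative_under_strong_drift(self, closed_system):
        ts = closed_system
        # steep linear potential: drift Peclet >> 1
        V = 0.5 * (1 - ts.mesh.nodes[:, 1] / (100 * NM))
        c = [np.full(ts.n_cells, 10.0), np.full(ts.n_cells, 10.0)]
        out = ts.advance_block(c, V, 5e-10, 0.2)
        for o in out:
            assert o.min() >= 0.0

    def test_axial_step_profile_matches_diffusion_series(self, closed_system):
        # 1D heat-kernel series for an initial step in a closed column
        ts = closed_system
        L = 100 * NM
        z = ts.centroid[:, 1]
        c0 = np.where(z < L / 2, 20.0, 0.0)
        D = ts.species[0].diffusion_coefficient
        t_end = L**2 / (10 * D)
        V = np.zeros(ts.mesh.n_nodes)
        c = [c0.copy(), c0.copy()]
        n_blocks = 20
        for _ in range(n_blocks):
            c = ts.advance_block(c, V, t_end / n_blocks, 0.2)
        # zero-flux cosine series of the step
        series = np.full_like(z, 10.0)
        for n in range(1, 200):
            k = n * math.pi / L
            a_n = 2 * 20.0 / L * math.sin(n * math.pi / 2) / k
            series += a_n * np.cos(k * z) * math.exp(-D * k**2 * t_end)
        err = np.abs(c[0] - series).max() / 20.0
        assert err < 0.02


class TestSteadySolve:
    def test_zero_field_equal_ends_gives_bulk(self, column_system):
        ts = column_system
        c = ts.steady_solve(np.zeros(ts.mesh.n_nodes), 0)
        assert np.abs(c - 10.0).max() < 1e-4

    def test_uniform_field_steady_profile_carries_uniform_flux(self, column_system):
        # 1D drift-diffusion BVP with uniform field and equal Dirichlet
        # ends: the steady SG solution must carry the same current through
        # every axial plane (div j = 0 exactly in the discrete sense)
        ts = column_system
        L = 100 * NM
        V = 0.05 * (1 - ts.mesh.nodes[:, 1] / L)
        c = ts.steady_solve(V, 0)  # K+, z = +1
        prof = plane_currents(ts, V, [c, c])
        IK = prof.currents["K"]
        assert (IK.max() - IK.min()) <= 1e-10 * np.abs(IK).max() + 1e-30

    def test_steady_state_is_fixed_point_of_time_stepping(self, column_system):
        ts = column_system
        L = 100 * NM
        V = 0.05 * (1 - ts.mesh.nodes[:, 1] / L)
        c_star = [ts.steady_solve(V, i) for i in range(2)]
        out = ts.advance_block([c.copy() for c in c_star], V, 1e-9, 0.2)
        for o, c in zip(out, c_star):
            assert np.abs(o - c).max() < 1e-8 * 10.0

    def test_face_flux_antisymmetry_in_network(self, column_system):
        # flux computed with flipped orientation must negate exactly
        ts = column_system
        rng = np.random.default_rng(3)
        V = rng.uniform(-0.05, 0.05, ts.mesh.n_nodes)
        c = 10.0 + rng.uniform(-1, 1, ts.n_cells)
        q = ts.face_fluxes(V, c, 0)
        # rebuild with swapped face orientation
        ts_sw = TransportSystem(ts.mesh, ts.species, T)
        ts_sw.face_cells = ts.face_cells[:, ::-1]
        q_sw = ts_sw.face_fluxes(V, c, 0)
        assert np.allclose(q, -q_sw, rtol=1e-12, atol=1e-30)
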