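import math

import numpy as np
import pytest

from nanopnp.config import ValidationError, kcl_electrolyte
from nanopnp.constants import CONSTANTS, NM, thermal_voltage
from nanopnp.mesh import build_column_mesh, build_plate_mesh
from nanopnp.observables import (
    IVCurve,
    electrochemical_potential,
    face_average_polarization,
    ions_in_volume,
    mode_decomposition,
    plane_currents,
    polarization_charge_density,
)
from nanopnp.poisson import PoissonSolver, permittivity_field
from nanopnp.transport import TransportSystem

T = 298.15


@pytest.fixture(scope="module")
def column_system():
    mesh = build_column_mesh(100 * NM, 200 * NM, 8, 30)
    return TransportSystem(mesh, kcl_electrolyte(10.0).species, T)


class TestPlaneCurrents:
    def test_equilibrium_currents_vanish(self, column_system):
        ts = column_system
        prof = plane_currents(ts, np.zeros(ts.mesh.n_nodes), ts.bulk_concentrations())
        for I in prof.currents.values():
            assert np.abs(I).max() == 0.0

    def test_ohmic_column_matches_conductivity(self, column_system):
        # uniform bulk + linear V: I = sigma E A with Nernst-Einstein sigma
        ts = column_system
        dV, L, R = 0.1, 200 * NM, 100 * NM
        V = dV * (1 - ts.mesh.nodes[:, 1] / L)
        prof = plane_currents(ts, V, ts.bulk_concentrations())
        k = CONSTANTS
        sigma = (k.faraday**2 / (k.gas_constant * T)) * sum(
            s.charge_number**2 * s.bulk_concentration * s.diffusion_coefficient
            for s in ts.species
        )
        I_exact = sigma * (dV / L) * math.pi * R**2
        assert np.allclose(prof.total, I_exact, rtol=1e-6)
        # species partition by their conductivity share
        share_K = 1.95 / (1.95 + 2.03)
        assert np.allclose(prof.currents["K"], share_K * I_exact, rtol=1e-6)

    def test_total_is_sum_of_species(self, column_system):
        ts = column_system
        rng = np.random.default_rng(5)
        V = rng.uniform(-0.02, 0.02, ts.mesh.n_nodes)
        c = [10 + rng.uniform(-1, 1, ts.n_cells) for _ in range(2)]
        prof = plane_currents(ts, V, c)
        total = prof.currents["K"] + prof.currents["Cl"]
        assert np.array_equal(prof.total, total)


class TestModeDecomposition:
    def test_reconstruction_is_exact(self):
        rng = np.random.default_rng(2)
        jK, jCl = rng.normal(size=50), rng.normal(size=50)
        jc, jd = mode_decomposition(jK, jCl)
        assert np.allclose(jc + jd, jK, atol=1e-15)
        assert np.allclose(jc - jd, jCl, atol=1e-15)

    def test_equal_fluxes_pure_common_mode(self):
        j = np.ones(5)
        jc, jd = mode_decomposition(j, j)
        assert np.allclose(jd, 0) and np.allclose(jc, j)

    def test_opposite_fluxes_pure_differential_mode(self):
        j = np.ones(5)
        jc, jd = mode_decomposition(j, -j)
        assert np.allclose(jc, 0) and np.allclose(jd, j)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValidationError):
            mode_decomposition(np.ones(3), np.ones(4))


class TestElectrochemicalPotential:
    def test_bulk_at_zero_voltage_is_zero(self, column_system):
        ts = column_system
        E = electrochemical_potential(ts, np.zeros(ts.mesh.n_nodes), np.full(ts.n_cells, 10.0), 0)
        assert np.abs(E).max() == 0.0

    def test_boltzmann_distribution_cancels(self, column_system):
        # c = c_B exp(-z e V / kT) => E_ec identically zero
        ts = column_system
        V = 0.05 * np.sin(ts.mesh.nodes[:, 1] / (30 * NM))
        Vc = ts.cell_voltage(V)
        for idx, z in ((0, 1), (1, -1)):
            c = 10.0 * np.exp(-z * Vc / thermal_voltage(T))
            E = electrochemical_potential(ts, V, c, idx)
            assert np.abs(E).max() < 1e-25  # joules; kT ~ 4e-21

    def test_nonpositive_concentration_masked(self, column_system):
        ts = column_system
        c = np.full(ts.n_cells, 10.0)
        c[0] = 0.0
        E = electrochemical_potential(ts, np.zeros(ts.mesh.n_nodes), c, 0)
        assert np.isnan(E[0]) and np.isfinite(E[1:]).all()


class TestPolarizationCharge:
    def test_unbiased_uncharged_plate_has_no_polarization(self):
        mesh = build_plate_mesh(50 * NM, 100 * NM, 20 * NM, 2 * NM)
        solver = PoissonSolver(mesh, permittivity_field(mesh, 78.4, 7.5))
        V = solver.solve(np.zeros(mesh.n_triangles), None, 0.0, 0.0)
        sp = polarization_charge_density(V, mesh, solver, 7.5)
        assert np.abs(sp).max() == 0.0

    def test_biased_plate_matches_series_capacitor(self):
        # sigma_pol = eps0 epsr_m * (membrane voltage drop) / L_m
        mesh = build_plate_mesh(50 * NM, 100 * NM, 20 * NM, 2 * NM)
        solver = PoissonSolver(mesh, permittivity_field(mesh, 78.4, 7.5))
        V = solver.solve(np.zeros(mesh.n_triangles), None, 1.0, 0.0)
        sp = polarization_charge_density(V, mesh, solver, 7.5)
        Lm, em, ew, Lw = 20 * NM, 7.5, 78.4, 200 * NM
        dV_m = (Lm / em) / (Lm / em + Lw / ew)
        expect = CONSTANTS.vacuum_permittivity * em * dV_m / Lm
        left = face_average_polarization(mesh, sp, "left")
        right = face_average_polarization(mesh, sp, "right")
        assert abs(left) == pytest.approx(expect, rel=0.02)
        assert abs(right) == pytest.approx(expect, rel=0.02)
        assert left == pytest.approx(-right, rel=1e-6)


class TestIVCurve:
    def test_linear_curve_has_constant_conductances(self):
        V = np.linspace(-1, 1, 9)
        V = V[V != 0]
        G0 = 2e-9
        curve = IVCurve(V, G0 * V)
        assert np.allclose(curve.G[~np.isnan(curve.G)], G0)
        assert np.allclose(curve.g, G0)
        assert all(r == pytest.approx(1.0) for r in curve.rectification_ratio().values())

    def test_duplicate_bias_rejected(self):
        with pytest.raises(ValidationError):
            IVCurve([0.1, 0.1, 0.2], [1, 2, 3])

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValidationError):
            IVCurve([0.1], [1.0])

    def test_rectifying_synthetic_curve(self):
        V = np.array([-0.5, -0.25, 0.25, 0.5])
        I = np.where(V > 0, 2e-9 * V, 1e-9 * V)
        curve = IVCurve(V, I)
        ratios = curve.rectification_ratio()
        assert ratios[0.5] == pytest.approx(2.0)
        assert ratios[0.25] == pytest.approx(2.0)


class TestIonCounts:
    def test_uncharged_pore_holds_under_20_ions(self):
        from nanopnp.config import GeometrySpec, NumericalControls
        from nanopnp.mesh import build_mesh

        mesh = build_mesh(
            GeometrySpec(), NumericalControls(min_element_size=1 * NM, mesh_growth_ratio=1.45)
        )
        ts = TransportSystem(mesh, kcl_electrolyte(10.0).species, T)
        n = ions_in_volume(ts, ts.bulk_concentrations())
        # analytic: 2 c_B N_A pi r^2 L = 18.9 ions
        exact = 2 * 10.0 * CONSTANTS.avogadro * math.pi * (5 * NM) ** 2 * 20 * NM
        assert n == pytest.approx(exact, rel=1e-9)
        assert n < 20

    def test_count_linear_in_concentration(self, column_system):
        ts = column_system
        zr = (50 * NM, 150 * NM)
        n1 = ions_in_volume(ts, ts.bulk_concentrations(), z_range=zr)
        n2 = ions_in_volume(ts, [2 * c for c in ts.bulk_concentrations()], z_range=zr)
        assert n2 == pytest.approx(2 * n1, rel=1e-12)

    def test_zero_concentration_zero_count(self, column_system):
        ts = column_system
        n = ions_in_volume(ts, [np.zeros(ts.n_cells)] * 2, z_range=(0, 100 * NM))
        assert n == 0.0
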