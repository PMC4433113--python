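"""Shared heavy fixtures: converged scenario runs on the coarse desk-scale mesh.

The simulations are expensive (each bias point runs the dual-time-step
transient plus the accelerated steady-state loop), so every scenario is
solved once per session and inspected by several tests.
"""

from __future__ import annotations

import pytest

from nanopnp.config import ChargeSpec, NumericalControls, SimulationConfig
from nanopnp.constants import NM
from nanopnp.engine import PNPSimulation
from nanopnp.mesh import build_plate_mesh
from nanopnp.scenarios import preset, run_bias_point, with_mesh_profile

MESH_PROFILE = "coarse"


def _solve(name: str, biases) -> tuple[PNPSimulation, dict]:
    cfg = with_mesh_profile(preset(name).config, MESH_PROFILE)
    sim = PNPSimulation(cfg)
    eq = sim.initialize_equilibrium()
    results = {b: run_bias_point(sim, eq, b) for b in biases}
    return sim, {"equilibrium": eq, "results": results}


@pytest.fixture(scope="session")
def uncharged_run():
    """Uncharged cylindrical pore swept to +/-0.5 V."""
    return _solve("uncharged_cyl", (-0.5, -0.25, 0.25, 0.5))


@pytest.fixture(scope="session")
def a_uniform_run():
    """Uniformly charged (-50 mC/m^2) pore at +/-0.25 V."""
    return _solve("a_uniform", (-0.25, 0.25))


@pytest.fixture(scope="session")
def b_pore_run():
    """Pore-wall-only charge at increasing positive bias (limiting g)."""
    return _solve("b_pore_only", (0.25, 0.5, 0.75, 1.0))


@pytest.fixture(scope="session")
def c_asym_run():
    """Asymmetric charge map at +/-0.5 V (rectifying)."""
    return _solve("c_asymmetric", (-0.5, 0.5))


@pytest.fixture(scope="session")
def cone_run():
    """Uniformly charged 20-degree cone at +/-0.25 V."""
    return _solve("cone_uniform", (-0.25, 0.25))


@pytest.fixture(scope="session")
def flat_wall_equilibrium():
    """Charged pore-less membrane at 0 V: the double layer is 1D Gouy-Chapman.

    Refined wall-normal grading (0.25 nm) so the 3 nm screening layer is
    well resolved.
    """
    mesh = build_plate_mesh(20 * NM, 120 * NM, 20 * NM, 0.25 * NM, n_r=3)
    cfg = SimulationConfig(
        charges=ChargeSpec("a_uniform", -0.05),
        controls=NumericalControls(min_element_size=0.25 * NM),
    )
    sim = PNPSimulation(cfg, mesh=mesh)
    state = sim.initialize_equilibrium()
    return sim, state
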