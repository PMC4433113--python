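"""Named scenario presets and the I-V sweep driver.

The presets reproduce the studied systems: a 10 nm pore in a 20 nm nitride
membrane in 10 mM KCl, with the surface-charge configurations

- ``uncharged_cyl``:  no fixed charge
- ``a_uniform``:      -50 mC/m^2 on the pore wall and both membrane faces
- ``b_pore_only``:    -50 mC/m^2 on the pore wall only
- ``c_asymmetric``:   -50 mC/m^2 on the left face + left half of the wall
- ``cone_uniform`` / ``cone_pore_only``: as above with a 20 degree conical
  pore (large ~17 nm opening at the right)
- ``overlimiting_thin``: 10 nm pore in a 5 nm membrane, 100 mM KCl,
  -100 mC/m^2 asymmetric -- the configuration whose I-V curve shows an
  overlimiting conductance.

Each sweep bias point starts from the shared 0 V equilibrium state, runs a
time simulation of 20 RC constants (the "0.2 us" current), then the
accelerated steady-state solve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    MESH_PROFILES,
    ChargeSpec,
    GeometrySpec,
    SimulationConfig,
    ValidationError,
    kcl_electrolyte,
)
from .constants import MC_PER_M2, NM
from .engine import ConvergenceError, ConvergenceReport, PNPSimulation, SimulationState
from .observables import CurrentProfile, IVCurve

logger = logging.getLogger(__name__)

DEFAULT_BIASES = tuple(round(v, 10) for v in np.arange(-1.0, 1.001, 0.25) if abs(v) > 1e-12)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named, immutable simulation scenario with its bias list."""

    name: str
    config: SimulationConfig
    biases: tuple[float, ...] = DEFAULT_BIASES
    outputs: tuple[str, ...] = ("iv", "profiles")


def _cyl(charge_cfg: str, sigma: float) -> SimulationConfig:
    return SimulationConfig(charges=ChargeSpec(charge_cfg, sigma))


def _cone(charge_cfg: str, sigma: float) -> SimulationConfig:
    return SimulationConfig(
        geometry=GeometrySpec(opening_angle=20.0, large_opening_side="right"),
        charges=ChargeSpec(charge_cfg, sigma),
    )


_SIGMA = -50 * MC_PER_M2


def _presets() -> dict[str, ScenarioSpec]:
    return {
        "uncharged_cyl": ScenarioSpec("uncharged_cyl", _cyl("uncharged", 0.0)),
        "a_uniform": ScenarioSpec("a_uniform", _cyl("a_uniform", _SIGMA)),
        "b_pore_only": ScenarioSpec("b_pore_only", _cyl("b_pore_only", _SIGMA)),
        "c_asymmetric": ScenarioSpec("c_asymmetric", _cyl("c_asymmetric", _SIGMA)),
        "cone_uniform": ScenarioSpec("cone_uniform", _cone("a_uniform", _SIGMA)),
        "cone_pore_only": ScenarioSpec("cone_pore_only", _cone("b_pore_only", _SIGMA)),
        "overlimiting_thin": ScenarioSpec(
            "overlimiting_thin",
            SimulationConfig(
                geometry=GeometrySpec(membrane_thickness=5 * NM),
                electrolyte=kcl_electrolyte(100.0),
                charges=ChargeSpec("c_asymmetric", -100 * MC_PER_M2),
            ),
        ),
    }


def preset(name: str) -> ScenarioSpec:
    """Fetch a named scenario preset (a fresh immutable copy)."""
    table = _presets()
    if name not in table:
        raise ValidationError(
            f"unknown scenario {name!r}; valid: {', '.join(sorted(table))}"
        )
    return table[name]


def with_mesh_profile(config: SimulationConfig, profile: str) -> SimulationConfig:
    """Apply one of the documented mesh profiles (coarse/default/fine)."""
    if profile not in MESH_PROFILES:
        raise ValidationError(
            f"unknown mesh profile {profile!r}; valid: {', '.join(MESH_PROFILES)}"
        )
    p = MESH_PROFILES[profile]
    controls = replace(
        config.controls,
        min_element_size=p["min_element_size"],
        mesh_growth_ratio=p["mesh_growth_ratio"],
    )
    return replace(config, controls=controls)


# ---------------------------------------------------------------------------


@dataclass
class BiasResult:
    """Converged (or failed) result at one bias point."""

    bias: float
    I_time: float                       # total current after n_RC tau, A
    I_steady: float | None              # accelerated steady-state current, A
    species_steady: dict[str, float] | None
    report: ConvergenceReport | None
    profile_steady: CurrentProfile | None
    profile_time: CurrentProfile | None = None   # plane currents after n_RC tau
    state_steady: "SimulationState | None" = None
    failure: str | None = None


@dataclass
class SweepResult:
    """I-V sweep over a scenario's bias list."""

    scenario: str
    results: list[BiasResult]
    mesh_stats: dict = field(default_factory=dict)

    def iv_curve(self, which: str = "steady") -> IVCurve:
        ok = [r for r in self.results if r.failure is None]
        if which == "steady":
            return IVCurve([r.bias for r in ok], [r.I_steady for r in ok])
        return IVCurve([r.bias for r in ok], [r.I_time for r in ok])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {
                "V": r.bias,
                "I_time": r.I_time,
                "I_steady": r.I_steady,
                "converged": r.report.converged if r.report else False,
                "outer_iterations": r.report.outer_iterations if r.report else None,
            }
            if r.species_steady:
                for name, I in r.species_steady.items():
                    if name != "total":
                        row[f"I_{name}_steady"] = I
            rows.append(row)
        return pd.DataFrame(rows).sort_values("V").reset_index(drop=True)


def run_iv_sweep(
    scenario: ScenarioSpec,
    mesh_profile: str | None = None,
    biases: tuple[float, ...] | None = None,
) -> SweepResult:
    """Run the full sweep protocol for one scenario.

    Each bias starts from the scenario's shared 0 V equilibrium state; the
    current after the 20-tau time simulation and the accelerated steady
    current are both recorded.
    """
    config = scenario.config
    if mesh_profile is not None:
        config = with_mesh_profile(config, mesh_profile)
    sim = PNPSimulation(config)
    eq = sim.initialize_equilibrium()
    results: list[BiasResult] = []
    for bias in biases if biases is not None else scenario.biases:
        results.append(run_bias_point(sim, eq, bias))
    if all(r.failure is not None for r in results):
        raise ConvergenceError(
            f"all bias points failed for scenario {scenario.name}",
            next(r.report for r in results if r.report is not None),
        )
    return SweepResult(
        scenario=scenario.name,
        results=results,
        mesh_stats={
            "n_nodes": sim.mesh.n_nodes,
            "n_triangles": sim.mesh.n_triangles,
            "tau_RC": sim.tau_RC,
        },
    )


def run_bias_point(
    sim: PNPSimulation, equilibrium: SimulationState, bias: float
) -> BiasResult:
    """Time-simulate then steady-solve one bias point from equilibrium."""
    n = sim.config.controls
    state = equilibrium.copy()
    state, _ = sim.run_time_simulation(state, n.rc_multiples * sim.tau_RC, bias, 0.0)
    profile_time = sim.profile(state)
    I_time = sim.membrane_midplane_current(state)["total"]
    try:
        steady, report = sim.steady_state_solve(state, bias, 0.0)
    except ConvergenceError as exc:
        logger.warning("bias %.3g V failed to converge: %s", bias, exc)
        return BiasResult(
            bias=bias, I_time=I_time, I_steady=None, species_steady=None,
            report=exc.report, profile_steady=None, profile_time=profile_time,
            failure=str(exc),
        )
    species = sim.membrane_midplane_current(steady)
    return BiasResult(
        bias=bias,
        I_time=I_time,
        I_steady=species["total"],
        species_steady=species,
        report=report,
        profile_steady=sim.profile(steady),
        profile_time=profile_time,
        state_steady=steady,
    )


# ---------------------------------------------------------------------------


def report(
    result: SweepResult,
    out_dir: str | Path,
    plots: bool = True,
    fields: bool = False,
    sim: "PNPSimulation | None" = None,
) -> list[Path]:
    """Write iv.csv, profiles.csv, convergence.log, the I-V plot and,
    when ``fields`` is set and steady states were kept, one VTK file per
    bias with the voltage and concentration fields."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if fields and sim is not None:
        from .vtkio import cell_field_on_mesh, write_vtk

        for r in result.results:
            if r.state_steady is None:
                continue
            cell_data = {
                f"c_{s.name}": cell_field_on_mesh(
                    sim.mesh, sim.transport.cell_quads, c
                )
                for s, c in zip(sim.transport.species, r.state_steady.concentrations)
            }
            p = out / f"fields_{r.bias:+.3f}V.vtk"
            write_vtk(sim.mesh, p, point_data={"voltage": r.state_steady.voltage},
                      cell_data=cell_data)
            written.append(p)

    iv = result.to_frame()
    ok = [r for r in result.results if r.failure is None]
    if len(ok) >= 2:  # conductances need a bias grid
        curve = result.iv_curve("steady")
        gmap = dict(zip(curve.V, curve.g))
        Gmap = dict(zip(curve.V, curve.G))
        iv["G_steady"] = iv["V"].map(Gmap)
        iv["g_steady"] = iv["V"].map(gmap)
        ratio = curve.rectification_ratio()
        iv["rectification_ratio"] = iv["V"].map(lambda v: ratio.get(v, np.nan))
    p = out / "iv.csv"
    iv.to_csv(p, index=False)
    written.append(p)

    rows = []
    for r in result.results:
        if r.profile_steady is None:
            continue
        prof = r.profile_steady
        for k, z in enumerate(prof.z):
            row = {"V": r.bias, "z": z}
            for name, I in prof.currents.items():
                row[f"I_{name}"] = I[k]
            row["I_total"] = prof.total[k]
            rows.append(row)
    p = out / "profiles.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written.append(p)

    lines = [f"scenario {result.scenario}: {result.mesh_stats}"]
    for r in result.results:
        if r.report is not None:
            lines.append(
                f"V={r.bias:+.3f} V: outer={r.report.outer_iterations} "
                f"metric={r.report.metric:.4g} converged={r.report.converged}"
            )
        if r.failure:
            lines.append(f"V={r.bias:+.3f} V: FAILED: {r.failure}")
    p = out / "convergence.log"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)

    if plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        frame = result.to_frame()
        ax.plot(frame["V"], 1e9 * frame["I_time"], "o--", label="after 20 tau")
        ax.plot(frame["V"], 1e9 * frame["I_steady"], "s-", label="steady state")
        for col, style in (("I_K_steady", "^:"), ("I_Cl_steady", "v:")):
            if col in frame:
                ax.plot(frame["V"], 1e9 * frame[col], style, label=col.replace("_steady", ""))
        ax.set_xlabel("V_L - V_R (V)")
        ax.set_ylabel("I (nA)")
        ax.legend(fontsize=8)
        ax.set_title(result.scenario)
        fig.tight_layout()
        p = out / "iv.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    return written


def overlay_measured(result: SweepResult, csv_path: str | Path) -> pd.DataFrame:
    """Ratio table simulated/measured for a user-supplied I-V CSV (V, I).

    No fitting or rescaling: the measured currents are interpolated onto
    the simulated bias grid and the raw ratio reported.
    """
    meas = pd.read_csv(csv_path)
    if not {"V", "I"}.issubset(meas.columns):
        raise ValidationError("measured I-V CSV needs columns 'V' and 'I'")
    curve = result.iv_curve("steady")
    I_meas = np.interp(curve.V, meas["V"].to_numpy(), meas["I"].to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(I_meas != 0, curve.I / I_meas, np.nan)
    return pd.DataFrame({"V": curve.V, "I_sim": curve.I, "I_measured": I_meas, "ratio": ratio})
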