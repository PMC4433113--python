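"""Time-dependent PNP integration and the accelerated steady-state solve.

Two algorithms drive every simulation:

1. **Dual-time-step integration.**  The Poisson equation is re-solved every
   ``dt_P``, a fraction (default 1/40) of the RC time constant of the
   solution resistance in series with the membrane capacitance
   (tau ~ 1e-8 s for the canonical domain).  Between Poisson solves the
   concentrations advance explicitly with the much smaller transport step
   ``dt_NP``, a fraction (default 1/5) of dx_min^2/D of the fastest species.

2. **Steady-state acceleration.**  A time simulation relaxes the charged
   (differential) mode within ~20 tau, but the chargeless common mode
   co-diffuses on the far slower dx^2/D_int scale.  So after each time
   segment the steady transport equation div j_i = 0 is solved per species
   with the field frozen, the volume-averaged concentration change is
   averaged across the species pair and added to BOTH species -- a pure
   common-mode shift that leaves the Poisson solution untouched -- and the
   time simulation restarts.  Iteration stops when each species' current is
   uniform across all axial planes within 0.5% of the total current (or of
   the pore+access-resistance current estimate at 0.1 V for zero-bias runs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig, ValidationError
from .mesh import Mesh, SurfaceChargeMap, build_mesh, make_charge_map
from .observables import CurrentProfile, midplane_current, plane_currents
from .oracles import OracleContext, membrane_RC, pore_access_resistance
from .poisson import PoissonSolver, permittivity_field
from .transport import TransportSystem

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Outer iteration cap exceeded; carries the last ConvergenceReport."""

    def __init__(self, message: str, report: "ConvergenceReport"):
        super().__init__(message)
        self.report = report


def rc_time_constant(R: float, C: float) -> float:
    """tau = R * C (seconds)."""
    if R < 0 or C < 0:
        raise ValidationError("R and C must be nonnegative")
    return R * C


@dataclass(frozen=True)
class TimeSteppingPlan:
    """Realized dual time steps for one run."""

    tau_RC: float
    dt_P: float
    dt_NP: float
    inner_steps: int
    duration: float

    def __post_init__(self) -> None:
        if self.dt_NP > self.dt_P * (1 + 1e-12):
            raise ValidationError("transport step must not exceed the Poisson step")
        if self.inner_steps * self.dt_NP < self.dt_P * (1 - 1e-12):
            raise ValidationError("inner steps must tile the Poisson step")


@dataclass
class SimulationState:
    """Voltage field + per-species concentration fields at one time point."""

    time: float
    voltage: np.ndarray
    concentrations: list[np.ndarray]

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.time, self.voltage.copy(), [c.copy() for c in self.concentrations]
        )


@dataclass
class ConvergenceReport:
    """Plane-current uniformity at the end of a steady-state solve."""

    species_spread: dict[str, float]
    scale: float
    metric: float
    outer_iterations: int
    converged: bool


class PNPSimulation:
    """One configured scenario: mesh, Poisson operator, transport graph.

    Parameters
    ----------
    config : SimulationConfig
    mesh : Mesh, optional
        Pre-built mesh (otherwise built from the geometry spec and controls).
    """

    def __init__(self, config: SimulationConfig, mesh: Mesh | None = None):
        self.config = config
        self.mesh = mesh if mesh is not None else build_mesh(config.geometry, config.controls)
        eps = permittivity_field(
            self.mesh,
            config.permittivity_water,
            config.permittivity_membrane,
            config.constants.vacuum_permittivity,
        )
        self.poisson = PoissonSolver(self.mesh, eps)
        self.transport = TransportSystem(
            self.mesh,
            config.electrolyte.species,
            config.electrolyte.temperature,
            constants=config.constants,
        )
        self.charge_map: SurfaceChargeMap = make_charge_map(
            self.mesh, config.charges.configuration, config.charges.sigma
        )
        self.oracle_ctx = OracleContext(
            electrolyte=config.electrolyte,
            geometry=config.geometry,
            permittivity_water=config.permittivity_water,
            permittivity_membrane=config.permittivity_membrane,
            constants=config.constants,
        )
        R, C, tau = membrane_RC(self.oracle_ctx)
        self.tau_RC = tau

    # ------------------------------------------------------------------
    def stepping_plan(self, duration: float | None = None) -> TimeSteppingPlan:
        """Dual time steps realized on this mesh."""
        n = self.config.controls
        dt_P = n.poisson_step_fraction * self.tau_RC
        dt_NP = min(dt_P, self.transport.stability_dt(n.transport_step_fraction))
        inner = max(1, math.ceil(dt_P / dt_NP))
        return TimeSteppingPlan(
            tau_RC=self.tau_RC,
            dt_P=dt_P,
            dt_NP=dt_P / inner,
            inner_steps=inner,
            duration=duration if duration is not None else n.rc_multiples * self.tau_RC,
        )

    def solve_poisson(self, concentrations: list[np.ndarray], V_L: float, V_R: float) -> np.ndarray:
        rho = self.transport.charge_density(concentrations)
        return self.poisson.solve(rho, self.charge_map, V_L, V_R)

    def estimate_reference_current(self) -> float:
        """Current estimate at the reference voltage from pore + access resistance."""
        R = pore_access_resistance(self.oracle_ctx)
        return self.config.controls.reference_voltage / R

    # ------------------------------------------------------------------
    def initialize_equilibrium(self) -> SimulationState:
        """Zero-bias equilibrium: double layers built up around all charges.

        For an uncharged system the equilibrium is the exact uniform bulk;
        otherwise the accelerated steady-state solve is run at V = 0.
        """
        conc = self.transport.bulk_concentrations()
        V = self.solve_poisson(conc, 0.0, 0.0)
        state = SimulationState(time=0.0, voltage=V, concentrations=conc)
        if np.all(self.charge_map.sigma == 0.0):
            return state
        state, report = self.steady_state_solve(state, 0.0, 0.0)
        return state

    # ------------------------------------------------------------------
    def run_time_simulation(
        self,
        state: SimulationState,
        duration: float,
        V_L: float,
        V_R: float,
        snapshot_every: int = 0,
    ) -> tuple[SimulationState, list[tuple[float, CurrentProfile]]]:
        """Advance the coupled system for ``duration`` at fixed applied bias.

        Alternation per Poisson block: solve Poisson from the current
        concentrations, then advance the concentrations by the inner
        transport steps.  If ``snapshot_every`` > 0, a plane-current profile
        is recorded every that many blocks.
        """
        n = self.config.controls
        dt_P = n.poisson_step_fraction * self.tau_RC
        n_blocks = max(1, round(duration / dt_P))
        conc = [c.copy() for c in state.concentrations]
        t = state.time
        snapshots: list[tuple[float, CurrentProfile]] = []
        V = state.voltage
        for b in range(n_blocks):
            V = self.solve_poisson(conc, V_L, V_R)
            conc = self.transport.advance_block(conc, V, dt_P, n.transport_step_fraction)
            self._pin_bulk(conc)
            t += dt_P
            if snapshot_every and (b + 1) % snapshot_every == 0:
                snapshots.append((t, plane_currents(self.transport, V, conc)))
        V = self.solve_poisson(conc, V_L, V_R)
        return SimulationState(time=t, voltage=V, concentrations=conc), snapshots

    def _pin_bulk(self, conc: list[np.ndarray]) -> None:
        pinned = self.transport.pinned
        for c, s in zip(conc, self.transport.species):
            c[pinned] = s.bulk_concentration

    # ------------------------------------------------------------------
    def convergence_metric(
        self, profile: CurrentProfile, V_L: float, V_R: float
    ) -> tuple[float, float]:
        """(metric, scale): max per-species plane-current spread / scale.

        scale = |total current| for biased runs, else the estimated current
        at the reference voltage.
        """
        if len(profile.z) == 0:
            raise ValidationError("empty current profile")
        spreads = profile.species_spread()
        if abs(V_L - V_R) > 0:
            scale = float(np.abs(profile.total).max())
        else:
            scale = abs(self.estimate_reference_current())
        if scale <= 0:
            raise ValidationError("zero normalization scale for convergence metric")
        return max(spreads.values()) / scale, scale

    def steady_state_solve(
        self, state: SimulationState, V_L: float, V_R: float
    ) -> tuple[SimulationState, ConvergenceReport]:
        """Accelerated steady state from an initial state.

        Loop: time-simulate n_RC tau; check plane-current uniformity; if not
        converged, solve the frozen-field steady transport equation per
        species, apply the species-averaged volume-weighted mean
        concentration change as a common-mode shift to both species
        (field-invariant for the 1:-1 pair), and repeat.
        """
        n = self.config.controls
        duration = n.rc_multiples * self.tau_RC
        vol = self.transport.volume
        vtot = vol.sum()
        report = None
        for it in range(1, n.max_outer_iterations + 1):
            state, _ = self.run_time_simulation(state, duration, V_L, V_R)
            profile = plane_currents(self.transport, state.voltage, state.concentrations)
            metric, scale = self.convergence_metric(profile, V_L, V_R)
            report = ConvergenceReport(
                species_spread=profile.species_spread(),
                scale=scale,
                metric=metric,
                outer_iterations=it,
                converged=metric <= n.uniformity_tolerance,
            )
            logger.info(
                "steady-state outer iteration %d: uniformity metric %.4g (tol %.4g)",
                it, metric, n.uniformity_tolerance,
            )
            if report.converged:
                return state, report
            # frozen-field steady solves and the common-mode shift: the
            # per-cell average of the two species' changes is added to BOTH
            # species, so the space charge -- and hence the field -- is
            # untouched, while the chargeless (co-diffusion) mode jumps
            # straight to its steady profile
            shift = np.zeros(self.transport.n_cells)
            for i in range(len(self.transport.species)):
                c_star = self.transport.steady_solve(state.voltage, i)
                shift += c_star - state.concentrations[i]
            shift /= len(self.transport.species)
            for c in state.concentrations:
                c += shift
                np.clip(c, 0.0, None, out=c)
            self._pin_bulk(state.concentrations)
        raise ConvergenceError(
            f"steady state not reached in {n.max_outer_iterations} outer iterations "
            f"(last metric {report.metric:.3g})",
            report,
        )

    # ------------------------------------------------------------------
    def profile(self, state: SimulationState) -> CurrentProfile:
        return plane_currents(self.transport, state.voltage, state.concentrations)

    def membrane_midplane_current(self, state: SimulationState) -> dict[str, float]:
        z_mid = (
            0.5 * sum(self.mesh.membrane_z)
            if self.mesh.membrane_z is not None
            else 0.5 * (self.mesh.nodes[:, 1].min() + self.mesh.nodes[:, 1].max())
        )
        return midplane_current(self.profile(state), z_mid)
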