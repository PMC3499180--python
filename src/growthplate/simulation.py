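"""Incremental growth simulation of the loaded physis.

Each iteration spans one cell-turnover interval ``dt = h_max / G``.  Per
step the solver (1) computes the elastic stress state under the sustained
axial load, (2) evaluates the proliferative and hypertrophic growth-rate
tensors per chondrocyte column from the element-local axial stress, (3)
integrates the growth strain into per-zone elongations, (4) stretches the
mesh accordingly, and (5) advances the cell cycle: every hypertrophic cell
ages by ``dt``, the oldest (fully mature) cell undergoes apoptosis and a
newly divided proliferative cell enters the hypertrophic column.  The last
step is truncated so the total simulated time equals the requested duration
exactly; the truncated step integrates elongation without a turnover event.

By default the kinetic zone widths (l_p, l_h) and the time step stay at
their per-case setup values ("steady geometry"), which keeps the growth
rate steady over the simulated window while the mesh itself elongates;
setting ``steady_geometry=False`` lets the kinetic widths track the grown
mesh instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fem, kinetics
from .kinetics import ChondrocyteColumn
from .mesh import FEMesh, MeshRefinement, ZONES, build_domain, generate_mesh, update_geometry
from .parameters import (
    LoadCaseTable,
    PhysiologicalConstants,
    get_constants,
    get_load_case,
)

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "SimulationResult",
    "initialize",
    "step",
    "run",
    "growth_curve",
]

log = logging.getLogger("growthplate")


@dataclass(frozen=True)
class SimulationConfig:
    """User-facing knobs of one simulation run."""

    delta_sigma_n: float                 # MPa, sustained stress difference (tension +)
    duration: float = 23.0               # days
    steady_geometry: bool = True         # keep kinetic zone widths at setup values
    elements_per_column: int = 1         # lateral mesh refinement
    reserve_rows: int = 2
    bone_rows: int = 2
    snapshot_every: int = 0              # mesh snapshot cadence in steps; 0 = none
    interpolate_load_case: bool = False  # allow non-tabulated stress differences

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.elements_per_column < 1:
            raise ValueError("elements_per_column must be >= 1")


@dataclass
class SimulationState:
    config: SimulationConfig
    constants: PhysiologicalConstants
    load_case: LoadCaseTable
    mesh: FEMesh
    columns: list[ChondrocyteColumn]
    dt: float                 # days, full turnover interval
    h_p: float                # um
    t_E: float                # days
    l_p0: float               # um, setup proliferative width
    l_h0: float               # um, setup hypertrophic width
    t: float = 0.0            # days
    elongation: float = 0.0   # um, cumulative
    n_steps: int = 0
    history: list[dict] = field(default_factory=list)
    snapshots: list[tuple[float, FEMesh, np.ndarray]] = field(default_factory=list)

    @property
    def n_p(self) -> float:
        """Proliferation rate, cells/day: one division per turnover interval."""
        return 1.0 / self.dt


@dataclass
class SimulationResult:
    """Time series and summary of one run."""

    config: SimulationConfig
    series: pd.DataFrame      # t_days, elongation_um, G_um_per_day, l_p_um, l_h_um
    mean_growth_rate: float   # um/day, total elongation / duration
    final_mesh: FEMesh
    snapshots: list[tuple[float, FEMesh, np.ndarray]]


def initialize(config: SimulationConfig) -> SimulationState:
    """Build mesh and steady-state cell columns for the configured load case."""
    constants = get_constants()
    lc = get_load_case(config.delta_sigma_n, interpolate=config.interpolate_load_case)

    h_max = kinetics.max_hypertrophic_height(config.delta_sigma_n, constants.h_max_f)
    dt = kinetics.time_step(h_max, lc.G_stokes)
    n_p, n_h = lc.cells_per_column
    h_p = lc.proliferative_thickness / n_p  # columnar cells fill the zone
    t_E = n_h * dt

    geometry = build_domain(lc, constants)
    refinement = MeshRefinement(
        proliferative_rows=n_p,
        hypertrophic_rows=n_h,
        reserve_rows=config.reserve_rows,
        bone_rows=config.bone_rows,
        elements_per_column=config.elements_per_column,
    )
    mesh_ = generate_mesh(geometry, refinement, constants.columns, constants.column_spacing)

    columns = [
        kinetics.steady_state_column(n_p, n_h, h_p, h_max, dt)
        for _ in range(constants.columns)
    ]
    return SimulationState(
        config=config,
        constants=constants,
        load_case=lc,
        mesh=mesh_,
        columns=columns,
        dt=dt,
        h_p=h_p,
        t_E=t_E,
        l_p0=lc.proliferative_thickness,
        l_h0=lc.hypertrophic_thickness,
    )


def _column_sigma_n(state: SimulationState, sol: fem.FESolution) -> np.ndarray:
    """Mean axial stress over each column's cartilage elements, MPa."""
    col_map = state.mesh.element_column
    zones = state.mesh.element_zone
    columnar = col_map >= 0
    n_cols = state.constants.columns
    out = np.empty(n_cols)
    for c in range(n_cols):
        sel = columnar & (col_map == c) & np.isin(zones, (ZONES.index("hypertrophic"), ZONES.index("proliferative")))
        out[c] = sol.sigma_n[sel].mean()
    return out


def step(state: SimulationState, dt_eff: float | None = None) -> SimulationState:
    """Advance one iteration (optionally truncated to ``dt_eff`` days)."""
    full_step = dt_eff is None
    dt_eff = state.dt if dt_eff is None else dt_eff

    # (1) elastic solve under the sustained load
    bc = fem.default_supports(state.mesh, state.config.delta_sigma_n + state.constants.sigma_n_f)
    sol = fem.assemble_and_solve(state.mesh, bc)

    # (2) per-column kinetics from element-local axial stress
    if state.config.steady_geometry:
        l_p, l_h = state.l_p0, state.l_h0
    else:
        l_p = state.mesh.zone_thickness("proliferative")
        l_h = state.mesh.zone_thickness("hypertrophic")

    sigma_cols = _column_sigma_n(state, sol)
    rate_p = np.empty(len(state.columns))
    rate_h = np.empty(len(state.columns))
    for c, column in enumerate(state.columns):
        ds_local = kinetics.stress_difference(sigma_cols[c], state.constants.sigma_n_f)
        h_max_c = kinetics.max_hypertrophic_height(ds_local, state.constants.h_max_f)
        # refresh heights on the maturation ramp for the local stress state
        column.hypertrophic_cells = [
            (age, kinetics.chondrocyte_height(state.h_p, h_max_c, min(age, state.t_E), state.t_E))
            for age, _ in column.hypertrophic_cells
        ]
        d_p = kinetics.proliferation_strain_rate(state.n_p, state.h_p, l_p)
        d_h = kinetics.hypertrophy_strain_rate(column, state.h_p, l_h)
        rate_p[c] = d_p.rate_nn
        rate_h[c] = d_h.rate_nn

    # (3) growth increments per zone (column average), um
    inc_p = float(rate_p.mean()) * l_p * dt_eff
    inc_h = float(rate_h.mean()) * l_h * dt_eff

    # (4) stretch the mesh
    state.mesh = update_geometry(
        state.mesh, {"proliferative": inc_p, "hypertrophic": inc_h}
    )

    # (5) cell turnover: only on full intervals
    if full_step:
        for column in state.columns:
            aged = [(age + state.dt, h) for age, h in column.hypertrophic_cells]
            aged.pop()                       # oldest mature cell: apoptosis
            aged.insert(0, (state.dt, state.h_p))  # newly transitioned cell
            column.hypertrophic_cells = aged

    increment = inc_p + inc_h
    state.elongation += increment
    state.t += dt_eff
    state.n_steps += 1
    state.history.append(
        {
            "t_days": state.t,
            "elongation_um": state.elongation,
            "G_um_per_day": increment / dt_eff,
            "l_p_um": state.mesh.zone_thickness("proliferative"),
            "l_h_um": state.mesh.zone_thickness("hypertrophic"),
        }
    )
    if state.config.snapshot_every and state.n_steps % state.config.snapshot_every == 0:
        state.snapshots.append((state.t, state.mesh, sol.sigma_n.copy()))
    log.debug(
        "step %d: t=%.3f d, sigma_n in [%.4f, %.4f] MPa, increment %.3f um",
        state.n_steps, state.t, sol.sigma_n.min(), sol.sigma_n.max(), increment,
    )
    return state


def run(config: SimulationConfig) -> SimulationResult:
    """Run the incremental scheme for the configured duration."""
    state = initialize(config)
    log.info(
        "load case %+.1f MPa: dt=%.3f d, h_p=%.2f um, %d+%d cells/column",
        config.delta_sigma_n, state.dt, state.h_p,
        state.load_case.proliferative_cells, state.load_case.hypertrophic_cells,
    )
    n_full = int(math.floor(config.duration / state.dt + 1e-12))
    for _ in range(n_full):
        step(state)
    remainder = config.duration - n_full * state.dt
    if remainder > 1e-12:
        step(state, dt_eff=remainder)

    series = pd.DataFrame(
        state.history,
        columns=["t_days", "elongation_um", "G_um_per_day", "l_p_um", "l_h_um"],
    )
    mean_G = state.elongation / config.duration if config.duration > 0 else 0.0
    log.info(
        "finished %+.1f MPa: %.1f um over %.0f days -> G = %.1f um/day",
        config.delta_sigma_n, state.elongation, config.duration, mean_G,
    )
    return SimulationResult(
        config=config,
        series=series,
        mean_growth_rate=mean_G,
        final_mesh=state.mesh,
        snapshots=state.snapshots,
    )


def growth_curve(result: SimulationResult) -> np.ndarray:
    """(t days, cumulative elongation um) pairs, including the origin."""
    t = np.concatenate([[0.0], result.series["t_days"].to_numpy()])
    e = np.concatenate([[0.0], result.series["elongation_um"].to_numpy()])
    return np.column_stack([t, e])
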