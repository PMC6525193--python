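"""1D finite-volume reactive transport of the packed-bed bioreactor.

The column (default 4.5 cm diameter x 64 cm, 64 one-centimetre cells,
cell centres at (i - 0.5) cm with 1-based cell indices) carries dissolved
species by explicit upwind advection and central-difference dispersion,
with an advective influent boundary and a zero-dispersive-gradient outlet.
Biomass (and elemental sulfur) are immobile: they react but never advect or
disperse.  Transport and reaction are integrated by operator splitting —
sequential transport-then-reaction per global step by default, with a Strang
option — and the reaction operator integrates every cell's batch kinetics
with the same solver as the batch module, so a single-cell reaction step is
the batch simulation.

The experimental protocol is reproduced in two phases: a no-flow startup
integrated until the minimum sulfate over the column drops to 0.1 mM
(complete reduction), then the scheduled flow/influent program.  Port
readings average the configured cells (first port: cells 6 and 7; last
port: cells 62 and 63).  A cumulative per-species mass ledger (influx,
outflux, storage, reaction) is maintained for balance checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .batch import KineticParams, ReactionSystem
from .reactions import CommunityReaction

IMMOBILE_SPECIES = ("sulfur",)  # elemental sulfur stays where it forms

SECONDS_PER_DAY = 86400.0


class ScheduleError(ValueError):
    pass


@dataclass
class ColumnGrid:
    """Geometry and transport properties of the 1D column."""

    length_cm: float = 64.0
    n_cells: int = 64
    diameter_cm: float = 4.5
    porosity: float = 0.375
    dispersivity_cm: float = 0.1
    molecular_diffusion_m2_s: float = 1e-9

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity must be in (0, 1)")
        if self.dispersivity_cm < 0 or self.molecular_diffusion_m2_s < 0:
            raise ValueError("dispersion parameters must be >= 0")

    @property
    def dx_cm(self) -> float:
        return self.length_cm / self.n_cells

    @property
    def area_cm2(self) -> float:
        return math.pi * (self.diameter_cm / 2.0) ** 2

    @property
    def cell_pore_volume_l(self) -> float:
        return self.porosity * self.area_cm2 * self.dx_cm / 1000.0

    @property
    def cell_centers_cm(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.dx_cm

    def pore_velocity_cm_s(self, flow_ml_h: float) -> float:
        return flow_ml_h / 3600.0 / (self.area_cm2 * self.porosity)

    def dispersion_cm2_s(self, flow_ml_h: float) -> float:
        v = self.pore_velocity_cm_s(flow_ml_h)
        return self.molecular_diffusion_m2_s * 1e4 + self.dispersivity_cm * v

    def travel_time_days(self, distance_cm: float, flow_ml_h: float) -> float:
        """Advective travel time over ``distance_cm`` at the given flow."""
        return distance_cm / self.pore_velocity_cm_s(flow_ml_h) / SECONDS_PER_DAY


@dataclass
class PortSpec:
    """1-based cell indices averaged per sampling port."""

    ports: dict[int, tuple[int, ...]] = field(
        default_factory=lambda: {1: (6, 7), 5: (62, 63)}
    )

    def validate(self, grid: ColumnGrid):
        for port, cells in self.ports.items():
            for c in cells:
                if not 1 <= c <= grid.n_cells:
                    raise ValueError(f"port {port}: cell {c} outside grid")


@dataclass
class Schedule:
    """Piecewise-constant flow and influent program.

    ``steps`` is a list of (t_start_days, flow_ml_h, {species: mM}); each
    step holds from its start time to the next step's start.
    """

    steps: list[tuple[float, float, dict[str, float]]]

    def __post_init__(self):
        times = [s[0] for s in self.steps]
        if not times or any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ScheduleError("schedule times must be strictly increasing")
        if times[0] != 0.0:
            raise ScheduleError("schedule must start at t = 0")
        for _, q, conc in self.steps:
            if q < 0 or any(v < 0 for v in conc.values()):
                raise ScheduleError("flow and concentrations must be >= 0")

    def at(self, t_days: float) -> tuple[float, dict[str, float]]:
        if t_days < 0:
            raise ScheduleError(f"time {t_days} before schedule start")
        current = self.steps[0]
        for step in self.steps:
            if step[0] <= t_days:
                current = step
            else:
                break
        return current[1], current[2]

    @property
    def end_day(self) -> float:
        return self.steps[-1][0]


def default_flow_schedule(
    sulfate_mM: float = 10.0,
    lactate_mM: float = 25.0,
    ammonium_mM: float = 1.0,
    horizon_days: float = 120.0,
) -> Schedule:
    """Reconstruction of the flow-experiment program (editable, not measured):
    flow ramps 0.5 -> 9 ml/h by +0.5 ml/h per day, nitrate steps
    2.5/5/10/15/17.5/20 mM anchored at days 21/40/60/86/100/110."""
    base = {"sulfate": sulfate_mM, "lactate": lactate_mM, "ammonium": ammonium_mM}
    steps: list[tuple[float, float, dict[str, float]]] = []
    nitrate_steps = [(0.0, 0.0), (21.0, 2.5), (40.0, 5.0), (60.0, 10.0), (86.0, 15.0), (100.0, 17.5), (110.0, 20.0)]
    change_days = sorted({float(d) for d in range(18)} | {d for d, _ in nitrate_steps})
    for day in change_days:
        if day > horizon_days:
            break
        flow = min(0.5 + 0.5 * day, 9.0)
        nitrate = [n for d, n in nitrate_steps if d <= day][-1]
        steps.append((day, flow, {**base, "nitrate": nitrate}))
    return Schedule(steps)


def constant_schedule(
    flow_ml_h: float, influent_mM: dict[str, float], t_start: float = 0.0
) -> Schedule:
    return Schedule([(t_start, flow_ml_h, dict(influent_mM))])


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------


def transport_step(
    conc: np.ndarray,
    grid: ColumnGrid,
    flow_ml_h: float,
    c_in: np.ndarray,
    dt_s: float,
    cfl: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance mobile concentrations one step; returns (conc, influx, outflux).

    ``conc`` has shape (n_cells, n_species) in mol/l; ``c_in`` the influent
    concentrations.  Explicit upwind advection + central dispersion, flux
    form, sub-cycled to honour the explicit stability limit.  Influx/outflux
    are moles crossing the inlet/outlet faces during the step, so discrete
    mass balance holds to round-off.
    """
    conc = np.array(conc, dtype=float)
    q_l_s = flow_ml_h / 3600.0 / 1000.0  # volumetric flow, l/s
    vp = grid.cell_pore_volume_l
    disp = grid.dispersion_cm2_s(flow_ml_h)
    disp_l_s = grid.porosity * grid.area_cm2 * disp / grid.dx_cm / 1000.0  # l/s
    rate = q_l_s / vp + 2.0 * disp_l_s / vp
    if rate <= 0.0:
        return conc, np.zeros(conc.shape[1]), np.zeros(conc.shape[1])
    n_sub = max(1, int(np.ceil(dt_s * rate / cfl)))
    dt = dt_s / n_sub
    influx = np.zeros(conc.shape[1])
    outflux = np.zeros(conc.shape[1])
    for _ in range(n_sub):
        # face advective fluxes (mol/s): upwind = upstream cell
        f_in = q_l_s * c_in
        f_adv = q_l_s * conc  # flux leaving each cell downstream
        f_disp = -disp_l_s * np.diff(conc, axis=0)  # interior faces
        inflow = np.vstack([f_in[None, :], f_adv[:-1] + f_disp])
        outflow = np.vstack([f_adv[:-1] + f_disp, f_adv[-1:]])
        dconc = (inflow - outflow) * dt / vp
        conc = conc + dconc
        influx += f_in * dt
        outflux += f_adv[-1] * dt
    return conc, influx, outflux


def reaction_step(
    state: np.ndarray,
    system: ReactionSystem,
    dt_s: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate every cell's batch kinetics over ``dt_s`` (cells independent).

    ``state`` has shape (n_cells, n_state) with the batch module's state
    layout; uses the same stacked solver as the batch simulator, so for a
    single cell this *is* the batch simulation.
    """
    if dt_s == 0.0:
        return np.array(state, dtype=float)
    out = system.integrate(np.asarray(state, dtype=float).ravel(), np.array([0.0, dt_s]), rtol=rtol, atol=atol)
    return out[-1].reshape(np.shape(state))


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------


@dataclass
class MassLedger:
    """Cumulative per-species moles for global balance checks."""

    influx: dict[str, float]
    outflux: dict[str, float]
    reacted: dict[str, float]  # net production by reaction (signed)
    initial_storage: dict[str, float]

    def closure(self, final_storage: dict[str, float], sp: str) -> float:
        """Relative balance residual for one species."""
        lhs = self.initial_storage[sp] + self.influx[sp] - self.outflux[sp] + self.reacted[sp]
        scale = max(
            abs(self.influx[sp]), abs(self.outflux[sp]), abs(self.initial_storage[sp]),
            abs(final_storage[sp]), 1e-12,
        )
        return (lhs - final_storage[sp]) / scale


@dataclass
class ColumnResult:
    port_series: pd.DataFrame  # tidy: time_d, port, species, value_mM
    ledger: MassLedger
    final_state: np.ndarray  # (n_cells, n_state)
    system: ReactionSystem
    grid: ColumnGrid
    startup_days: float
    profiles: pd.DataFrame | None = None  # optional snapshots: time_d, cell, ...


class ColumnModel:
    """Stateful column simulator used by :func:`run_column` and the
    mechanism-analysis sweeps."""

    def __init__(
        self,
        grid: ColumnGrid,
        network: list[CommunityReaction],
        params: dict[str, KineticParams],
        inhibition: bool = True,
        rtol: float = 1e-6,
        atol: float = 1e-9,
        splitting: str = "sequential",
    ):
        if splitting not in ("sequential", "strang"):
            raise ValueError("splitting must be 'sequential' or 'strang'")
        self.grid = grid
        self.system = ReactionSystem(network, params, inhibition=inhibition, grow_biomass=True)
        self.rtol = rtol
        self.atol = atol
        self.splitting = splitting
        sysm = self.system
        self.mobile = np.array([sp not in IMMOBILE_SPECIES for sp in sysm.species])
        # uniform initial biomass along the column, from each community's X0
        self.state = np.zeros((grid.n_cells, sysm.n_state))
        for j, rxn in enumerate(sysm.network):
            self.state[:, sysm.n_dyn + j] = params[rxn.name].x0_mol_per_l
        self.ledger = MassLedger(
            influx={sp: 0.0 for sp in sysm.species},
            outflux={sp: 0.0 for sp in sysm.species},
            reacted={sp: 0.0 for sp in sysm.species},
            initial_storage={},
        )

    def set_initial_conc(self, conc_mol_l: dict[str, float]):
        for sp, v in conc_mol_l.items():
            if sp in self.system.sp_index:
                self.state[:, self.system.sp_index[sp]] = v
        self.ledger.initial_storage = self.storage()

    def storage(self) -> dict[str, float]:
        """Moles of each dynamic species currently stored in the pore fluid."""
        vp = self.grid.cell_pore_volume_l
        return {
            sp: float(self.state[:, i].sum() * vp)
            for sp, i in self.system.sp_index.items()
        }

    def biomass_totals(self) -> dict[str, float]:
        vp = self.grid.cell_pore_volume_l
        return {
            n: float(self.state[:, self.system.n_dyn + j].sum() * vp)
            for j, n in enumerate(self.system.names)
        }

    # -- operators --------------------------------------------------------
    def _react(self, dt_s: float):
        before = self.state.copy()
        self.state = reaction_step(self.state, self.system, dt_s, rtol=self.rtol, atol=self.atol)
        vp = self.grid.cell_pore_volume_l
        delta = (self.state - before)[:, : self.system.n_dyn].sum(axis=0) * vp
        for sp, i in self.system.sp_index.items():
            self.ledger.reacted[sp] += float(delta[i])

    def _transport(self, dt_s: float, flow_ml_h: float, influent_mM: dict[str, float]):
        if flow_ml_h <= 0.0:
            return
        sysm = self.system
        mob = self.mobile
        c_in = np.array(
            [influent_mM.get(sp, 0.0) * 1e-3 for sp in sysm.species], dtype=float
        )[mob]
        conc = self.state[:, : sysm.n_dyn]
        new, influx, outflux = transport_step(
            conc[:, mob], self.grid, flow_ml_h, c_in, dt_s
        )
        conc[:, mob] = new
        for k, sp in enumerate(np.array(sysm.species)[mob]):
            self.ledger.influx[sp] += float(influx[k])
            self.ledger.outflux[sp] += float(outflux[k])

    def step(self, dt_s: float, flow_ml_h: float, influent_mM: dict[str, float]):
        if self.splitting == "strang":
            self._transport(dt_s / 2.0, flow_ml_h, influent_mM)
            self._react(dt_s)
            self._transport(dt_s / 2.0, flow_ml_h, influent_mM)
        else:
            self._transport(dt_s, flow_ml_h, influent_mM)
            self._react(dt_s)

    # -- sampling ---------------------------------------------------------
    def port_values(self, ports: PortSpec) -> dict[int, dict[str, float]]:
        out = {}
        for port, cells in ports.ports.items():
            idx = np.array(cells) - 1  # 1-based cells
            out[port] = {
                sp: float(self.state[idx, i].mean())
                for sp, i in self.system.sp_index.items()
            }
        return out


def run_column(
    grid: ColumnGrid,
    network: list[CommunityReaction],
    params: dict[str, KineticParams],
    schedule: Schedule,
    initial_conc_mM: dict[str, float] | None = None,
    ports: PortSpec | None = None,
    horizon_days: float | None = None,
    dt_days: float = 0.01,
    sample_every_days: float = 0.25,
    startup_threshold_mM: float = 0.1,
    max_startup_days: float = 30.0,
    inhibition: bool = True,
    splitting: str = "sequential",
    rtol: float = 1e-6,
    atol: float = 1e-9,
    skip_startup: bool = False,
    snapshot_every_days: float | None = None,
) -> ColumnResult:
    """Run the two-phase column experiment and sample the ports.

    Phase 1 integrates the no-flow startup until the minimum sulfate over
    the column reaches ``startup_threshold_mM`` (0.1 mM, i.e. complete
    reduction); phase 2 applies the flow/influent schedule.  Port series are
    sampled every ``sample_every_days`` of phase-2 time.
    """
    ports = ports or PortSpec()
    ports.validate(grid)
    if horizon_days is None:
        horizon_days = schedule.end_day + 10.0

    model = ColumnModel(
        grid, network, params, inhibition=inhibition, rtol=rtol, atol=atol, splitting=splitting
    )
    init = initial_conc_mM
    if init is None:
        _, first_influent = schedule.at(0.0)
        init = dict(first_influent)
    model.set_initial_conc({sp: v * 1e-3 for sp, v in init.items()})

    sysm = model.system
    dt_s = dt_days * SECONDS_PER_DAY
    i_sulf = sysm.sp_index.get("sulfate")

    # phase 1: batchwise startup (no flow)
    startup_days = 0.0
    if not skip_startup and i_sulf is not None:
        while startup_days < max_startup_days:
            if model.state[:, i_sulf].min() <= startup_threshold_mM * 1e-3:
                break
            model._react(dt_s)
            startup_days += dt_days

    # phase 2: scheduled flow
    rows = []
    snapshots = []
    n_steps = int(round(horizon_days / dt_days))
    next_sample = 0.0
    next_snap = 0.0 if snapshot_every_days else np.inf

    def sample(t_days):
        for port, vals in model.port_values(ports).items():
            for sp, v in vals.items():
                rows.append((t_days, port, sp, v * 1e3))

    sample(0.0)
    next_sample = sample_every_days
    for k in range(n_steps):
        t = k * dt_days
        flow, influent = schedule.at(t)
        model.step(dt_s, flow, influent)
        t_next = (k + 1) * dt_days
        if t_next + 1e-9 >= next_sample:
            sample(t_next)
            next_sample += sample_every_days
        if snapshot_every_days and t_next + 1e-9 >= next_snap:
            for c in range(grid.n_cells):
                for sp, i in sysm.sp_index.items():
                    snapshots.append((t_next, c + 1, sp, model.state[c, i] * 1e3))
            next_snap += snapshot_every_days

    port_series = pd.DataFrame(rows, columns=["time_d", "port", "species", "value_mM"])
    profiles = (
        pd.DataFrame(snapshots, columns=["time_d", "cell", "species", "value_mM"])
        if snapshots
        else None
    )
    return ColumnResult(
        port_series=port_series,
        ledger=model.ledger,
        final_state=model.state,
        system=sysm,
        grid=grid,
        startup_days=startup_days,
        profiles=profiles,
    )


def estimate_influent_sulfate(port_series: pd.DataFrame, window: tuple[float, float]) -> float:
    """Mean of (sulfate + sulfide) over a time window of a port series (mM).

    The experimental influent sulfate is not reported directly; under sulfur
    conservation the sum of sulfate and sulfide at any port equals the
    injected sulfate once the front has passed, so averaging the sum over
    consecutive samples estimates the injection concentration.
    """
    lo, hi = window
    sel = port_series[(port_series["time_d"] >= lo) & (port_series["time_d"] <= hi)]
    sulf = sel[sel["species"] == "sulfate"].groupby("time_d")["value_mM"].mean()
    h2s = sel[sel["species"] == "sulfide"].groupby("time_d")["value_mM"].mean()
    total = sulf.add(h2s, fill_value=0.0)
    if len(total) < 1:
        raise ValueError("window contains no samples")
    return float(total.mean())
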