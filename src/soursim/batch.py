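"""Well-mixed batch kinetics of a community reaction network.

Each community grows at a Monod rate with optional product inhibition,

    r = mu_max * X * C_d/(C_d+K_d) * C_a/(C_a+K_a) * I/(C_inh+I) - b * X

(mol biomass l-1 s-1); the inhibition factor is present only for communities
with a declared inhibitor (nitrite on SRB).  Species turn over at the
community's stoichiometric coefficients per mole of biomass synthesized,
driven by the gross growth term; the endogenous decay term ``b*X`` removes
biomass only.  Batch simulations default to frozen biomass, matching heavily
inoculated short experiments where net growth is negligible while substrate
turnover is not.

To keep the ODE right-hand side Lipschitz while preventing concentrations
from running negative, every reaction is gated by a smooth quadratic cutoff
on each of the species it consumes, active below ~1e-12 mol/l.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import ODEintWarning, odeint, solve_ivp

from .chem import DYNAMIC_SPECIES, mg_per_l_to_mol_per_l
from .numerics import HAVE_NUMBA, kinetics_rhs
from .reactions import CommunityReaction

CUTOFF = 1e-12  # mol/l; smooth non-negativity gate scale


class IntegrationError(RuntimeError):
    pass


@dataclass
class KineticParams:
    """Monod parameters of one community (SI units: 1/s and mol/l).

    ``X0`` is the initial biomass in mg/l (the experimental scale); ``I`` is
    the product-inhibition coefficient, used only when the community's
    reaction declares an inhibitor species.
    """

    mu_max: float  # 1/s
    K_d: float  # mol/l
    K_a: float  # mol/l
    I: float | None = None  # mol/l
    b: float = 0.0  # 1/s
    X0: float = 0.0  # mg/l

    def __post_init__(self):
        for attr in ("mu_max", "K_d", "K_a", "b", "X0"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.I is not None and self.I <= 0:
            raise ValueError("I must be > 0 when set")

    @property
    def x0_mol_per_l(self) -> float:
        return mg_per_l_to_mol_per_l(self.X0, "biomass")


def monod_rate(p: KineticParams, X: float, C_d: float, C_a: float, C_inhibitor: float = 0.0) -> float:
    """Net Monod growth rate of one community (mol biomass/l/s)."""
    for v, nm in ((X, "X"), (C_d, "C_d"), (C_a, "C_a"), (C_inhibitor, "C_inhibitor")):
        if v < 0:
            raise ValueError(f"{nm} must be >= 0")
    rate = p.mu_max * X * C_d / (C_d + p.K_d) * C_a / (C_a + p.K_a)
    if p.I is not None:
        rate *= p.I / (C_inhibitor + p.I)
    return rate - p.b * X


class ReactionSystem:
    """Precompiled arrays for a network of community reactions.

    The state vector per reactor (cell) is ``[dynamic species..., biomass per
    community...]`` in mol/l.  The same right-hand side serves the batch
    simulator and the per-cell reaction operator of the column model; several
    independent reactors can be stacked and integrated in one solver call.
    """

    def __init__(
        self,
        network: list[CommunityReaction],
        params: dict[str, KineticParams],
        inhibition: bool = True,
        grow_biomass: bool = False,
    ):
        self.network = list(network)
        self.params = params
        self.inhibition = inhibition
        self.grow_biomass = grow_biomass

        used = set()
        for rxn in self.network:
            used.update(rxn.stoich)
            if inhibition and rxn.inhibitor is not None:
                used.add(rxn.inhibitor)
        self.species = [s for s in DYNAMIC_SPECIES if s in used]
        self.sp_index = {s: i for i, s in enumerate(self.species)}
        self.names = [r.name for r in self.network]

        n_rxn = len(self.network)
        n_dyn = len(self.species)
        self.n_dyn = n_dyn
        self.n_state = n_dyn + n_rxn

        self.nu = np.zeros((n_rxn, n_dyn))
        self.donor_idx = np.zeros(n_rxn, dtype=int)
        self.acceptor_idx = np.zeros(n_rxn, dtype=int)
        self.inhib_idx = np.full(n_rxn, -1, dtype=int)
        self.mu = np.zeros(n_rxn)
        self.Kd = np.zeros(n_rxn)
        self.Ka = np.zeros(n_rxn)
        self.I = np.full(n_rxn, np.inf)
        self.b = np.zeros(n_rxn)
        for j, rxn in enumerate(self.network):
            p = params[rxn.name]
            for sp, c in rxn.stoich.items():
                if sp in self.sp_index:
                    self.nu[j, self.sp_index[sp]] = c
            self.donor_idx[j] = self.sp_index[rxn.donor_species]
            self.acceptor_idx[j] = self.sp_index[rxn.acceptor_species]
            if inhibition and rxn.inhibitor is not None:
                self.inhib_idx[j] = self.sp_index[rxn.inhibitor]
                if p.I is None:
                    raise ValueError(f"community {rxn.name} needs an inhibition coefficient I")
                self.I[j] = p.I
            self.mu[j] = p.mu_max
            self.Kd[j] = p.K_d
            self.Ka[j] = p.K_a
            self.b[j] = p.b
        self.consumed = self.nu < 0  # (n_rxn, n_dyn) gating mask

    # -- state helpers -----------------------------------------------------
    def initial_state(self, conc: dict[str, float]) -> np.ndarray:
        """State vector from a species->mol/l map plus the params' X0."""
        y = np.zeros(self.n_state)
        for sp, v in conc.items():
            if sp in self.sp_index:
                y[self.sp_index[sp]] = v
        for j, rxn in enumerate(self.network):
            y[self.n_dyn + j] = self.params[rxn.name].x0_mol_per_l
        return y

    # -- vectorized kinetics ----------------------------------------------
    def gross_rates(self, C: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Gross growth rates, shape (n_cells, n_rxn); C is (n_cells, n_dyn)."""
        Cp = np.maximum(C, 0.0)
        Cd = Cp[:, self.donor_idx]
        Ca = Cp[:, self.acceptor_idx]
        r = np.maximum(X, 0.0) * self.mu * Cd / (Cd + self.Kd) * Ca / (Ca + self.Ka)
        for j in np.flatnonzero(self.inhib_idx >= 0):
            Ci = Cp[:, self.inhib_idx[j]]
            r[:, j] *= self.I[j] / (Ci + self.I[j])
        # smooth non-negativity gate on every consumed species
        s = Cp * Cp / (C * C + CUTOFF * CUTOFF)
        gate = np.prod(np.where(self.consumed[None, :, :], s[:, None, :], 1.0), axis=2)
        return r * gate

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        if HAVE_NUMBA:
            out = np.empty_like(y)
            return kinetics_rhs(
                y,
                out,
                y.size // self.n_state,
                self.n_dyn,
                self.n_state,
                self.nu,
                self.donor_idx,
                self.acceptor_idx,
                self.inhib_idx,
                self.mu,
                self.Kd,
                self.Ka,
                self.I,
                self.b,
                self.consumed,
                self.grow_biomass,
            )
        return self.rhs_numpy(t, y)

    def rhs_numpy(self, t: float, y: np.ndarray) -> np.ndarray:
        n_cells = y.size // self.n_state
        Y = y.reshape(n_cells, self.n_state)
        C = Y[:, : self.n_dyn]
        X = Y[:, self.n_dyn :]
        r = self.gross_rates(C, X)
        dC = r @ self.nu
        if self.grow_biomass:
            dX = r - self.b * np.maximum(X, 0.0)
        else:
            dX = np.zeros_like(X)
        return np.concatenate([dC, dX], axis=1).ravel()

    def integrate(
        self,
        y0: np.ndarray,
        t_grid: np.ndarray,
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ) -> np.ndarray:
        """Integrate stacked reactors; returns array (n_times, n_states).

        Uses LSODA with a banded Jacobian structure (reactors are mutually
        independent, so the Jacobian is block diagonal).
        """
        t_grid = np.asarray(t_grid, dtype=float)
        band = self.n_state - 1
        sol = solve_ivp(
            self.rhs,
            (t_grid[0], t_grid[-1]),
            np.asarray(y0, dtype=float).ravel(),
            method="LSODA",
            t_eval=t_grid,
            rtol=rtol,
            atol=atol,
            lband=band,
            uband=band,
        )
        if not sol.success:  # pragma: no cover - solver diagnostics
            raise IntegrationError(f"ODE integration failed: {sol.message}")
        return sol.y.T

    def integrate_capped(
        self,
        y0: np.ndarray,
        t_grid: np.ndarray,
        rtol: float = 1e-6,
        atol: float = 1e-9,
        mxstep: int = 3000,
    ) -> np.ndarray:
        """Banded LSODA integration with a hard work cap per output interval.

        Used inside population-based fitting, where occasional pathological
        parameter candidates would otherwise stall the search; exceeding the
        cap raises :class:`IntegrationError`, which the optimizer treats as
        an infeasible candidate.
        """
        band = self.n_state - 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ODEintWarning)
            out, info = odeint(
                lambda y, t: self.rhs(t, y),
                np.asarray(y0, dtype=float).ravel(),
                np.asarray(t_grid, dtype=float),
                ml=band,
                mu=band,
                rtol=rtol,
                atol=atol,
                mxstep=mxstep,
                full_output=True,
            )
        if info["message"] != "Integration successful.":
            raise IntegrationError(info["message"])
        return out


def simulate_batch(
    network: list[CommunityReaction],
    params: dict[str, KineticParams],
    initial_conc: dict[str, float],
    t_grid: np.ndarray,
    grow_biomass: bool = False,
    inhibition: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Simulate one well-mixed batch; returns a wide table (rows = t_grid).

    Columns are dynamic species (mol/l) plus ``X_<community>`` biomass
    columns (mol/l).  ``initial_conc`` is species -> mol/l; initial biomass
    comes from each community's ``X0``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    sys = ReactionSystem(network, params, inhibition=inhibition, grow_biomass=grow_biomass)
    y0 = sys.initial_state(initial_conc)
    out = sys.integrate(y0, t_grid, rtol=rtol, atol=atol)
    cols = list(sys.species) + [f"X_{n}" for n in sys.names]
    return pd.DataFrame(out, index=pd.Index(t_grid, name="time_s"), columns=cols)


def simulate_experiments(
    system: ReactionSystem,
    initial_concs: list[dict[str, float]],
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Simulate several batches sharing one time grid in a single solver call.

    Returns array (n_experiments, n_times, n_state).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    y0 = np.stack([system.initial_state(c) for c in initial_concs])
    out = system.integrate(y0.ravel(), t_grid, rtol=rtol, atol=atol)
    n_exp = len(initial_concs)
    return out.reshape(len(t_grid), n_exp, system.n_state).transpose(1, 0, 2)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

#: Species entering the fit score by default.  Lactate is excluded (its decay
#: in the calibration experiments is partly fermentative, which the network
#: deliberately does not model); ammonium is included because it is the only
#: observable separating nitrite reduction to ammonium from reduction to N2.
DEFAULT_SSE_SPECIES = ("sulfate", "sulfide", "nitrate", "nitrite", "ammonium")


def _range_weight(values) -> float:
    """Residual scale for one species: its observed range, floored at 5% of
    its magnitude (constant channels would otherwise get zero weight) and at
    1e-9 mol/l."""
    values = np.asarray(values, dtype=float)
    rng = float(values.max() - values.min())
    return max(rng, 0.05 * float(np.abs(values).max()), 1e-9)


@dataclass
class FitScore:
    """Sum of squared (range-normalized) residuals and its breakdown."""

    sse: float
    per_species_sse: dict[str, float] = field(default_factory=dict)
    rsse: float | None = None  # percent, filled during screening


def sse(
    model_trajs: dict[str, pd.DataFrame],
    data: pd.DataFrame,
    species: tuple[str, ...] = DEFAULT_SSE_SPECIES,
    weighting: str = "range",
) -> FitScore:
    """Score model trajectories against tidy observations.

    ``data`` has columns (experiment_id, time_s, species, value) in mol/l;
    ``model_trajs`` maps experiment_id to a wide table as produced by
    :func:`simulate_batch`.  Model values are linearly interpolated onto the
    observation times.  With ``weighting='range'`` residuals of each species
    are divided by that species' observed range over the whole data set, so
    species measured on very different molar scales contribute comparably.
    """
    if data.empty:
        raise ValueError("no observations to score")
    data = data[data["species"].isin(species)]
    if data.empty:
        raise ValueError("no observations for the scored species")
    weights = {}
    for sp, grp in data.groupby("species"):
        weights[sp] = _range_weight(grp["value"]) if weighting == "range" else 1.0
    per: dict[str, float] = {}
    for (exp_id, sp), grp in data.groupby(["experiment_id", "species"]):
        traj = model_trajs[exp_id]
        if sp not in traj.columns:
            model_vals = np.zeros(len(grp))
        else:
            model_vals = np.interp(grp["time_s"].to_numpy(), traj.index.to_numpy(), traj[sp].to_numpy())
        res = (model_vals - grp["value"].to_numpy()) / weights[sp]
        per[sp] = per.get(sp, 0.0) + float(res @ res)
    return FitScore(sse=float(sum(per.values())), per_species_sse=per)


def rsse_percent(sse_values: list[float]) -> list[float]:
    """Relative SSE in percent: 100 * (SSE_i - min) / min."""
    least = min(sse_values)
    if least <= 0:
        return [0.0 if v == least else float("inf") for v in sse_values]
    return [100.0 * (v - least) / least for v in sse_values]
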