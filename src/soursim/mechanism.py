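"""Mechanism dissection: variant toggles, MINC, RINC and the R-ratio.

The nitrate-treatment literature distinguishes three inhibition mechanisms:
nitrite inhibition of SRB, biocompetition for the shared electron donor, and
sulfur cycling (re-oxidation of sulfide by NRSOB).  They are separated by
*variant* simulations of a fitted model: the full model; the same model with
the nitrite-inhibition factor removed; and the model with the nitrate
reducers removed entirely (SRB only).

Two design metrics summarize nitrate demand:

* MINC (minimum inhibitory nitrate concentration) is pure stoichiometry —
  the nitrate needed to oxidize, via sulfur cycling, all the sulfate the
  available electron donor could reduce:
  ``MINC = lactate * Y(sulfate/lactate) / Y(sulfide/nitrate, total)``.
* RINC (required inhibitory nitrate concentration) is dynamic — the lowest
  injected nitrate keeping quasi-steady sulfide below a threshold at a given
  observation distance when nitrite inhibition acts.  It is found by
  bisection over column simulations and grows with distance, because nitrite
  must be maintained along the whole flow path.

R, the ratio of the nitrite-reduction to nitrate-reduction maximum turnover
rates, is evaluated at substrate saturation with the communities' initial
biomass: ``R = (mu2 X2 |nu_a2|) / (mu1 X1 |nu_a1|)``; low R lets nitrite
accumulate and makes treatment effective.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .batch import KineticParams, simulate_batch
from .column import ColumnGrid, PortSpec, Schedule, run_column
from .reactions import CommunityReaction, stoich_yield


class VariantConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimVariant:
    """A toggled model variant (the standard dissection triplet: full model /
    inhibition off / nitrate reducers removed)."""

    name: str
    inhibition_on: bool = True
    exclude_communities: tuple[str, ...] = ()


FULL_MODEL = SimVariant("full")
NO_INHIBITION = SimVariant("no-inhibition", inhibition_on=False)


def no_nitrate_reducers(network: list[CommunityReaction]) -> SimVariant:
    """Variant dropping every community except SRB (no biocompetition, no
    sulfur cycling; in batch this also removes nitrite inhibition since no
    nitrite is ever formed)."""
    names = tuple(r.name for r in network if r.name != "SRB")
    return SimVariant("srb-only", inhibition_on=True, exclude_communities=names)


def apply_variant(
    variant: SimVariant,
    network: list[CommunityReaction],
    params: dict[str, KineticParams],
) -> tuple[list[CommunityReaction], dict[str, KineticParams]]:
    present = {r.name for r in network}
    missing = set(variant.exclude_communities) - present
    if missing:
        raise VariantConfigError(f"cannot remove absent communities: {sorted(missing)}")
    net = [r for r in network if r.name not in variant.exclude_communities]
    pars = {r.name: params[r.name] for r in net}
    return net, pars


def run_variant_batch(
    variant: SimVariant,
    network: list[CommunityReaction],
    params: dict[str, KineticParams],
    initial_conc: dict[str, float],
    t_grid: np.ndarray,
    **kwargs,
) -> pd.DataFrame:
    """Simulate one batch under a variant; output tagged with the variant id."""
    net, pars = apply_variant(variant, network, params)
    df = simulate_batch(net, pars, initial_conc, t_grid, inhibition=variant.inhibition_on, **kwargs)
    df.attrs["variant"] = variant.name
    return df


def run_variant_column(
    variant: SimVariant,
    grid: ColumnGrid,
    network: list[CommunityReaction],
    params: dict[str, KineticParams],
    schedule: Schedule,
    **kwargs,
):
    net, pars = apply_variant(variant, network, params)
    result = run_column(grid, net, pars, schedule, inhibition=variant.inhibition_on, **kwargs)
    result.port_series.attrs["variant"] = variant.name
    return result


# ---------------------------------------------------------------------------
# MINC
# ---------------------------------------------------------------------------


def minc(
    lactate_mM: float,
    yield_sulfate_per_lactate: float,
    yield_sulfide_per_nitrate_total: float,
) -> float:
    """Minimum inhibitory nitrate concentration (mM), pure stoichiometry."""
    if yield_sulfate_per_lactate <= 0 or yield_sulfide_per_nitrate_total <= 0:
        raise ValueError("yields must be > 0")
    if lactate_mM < 0:
        raise ValueError("lactate concentration must be >= 0")
    return lactate_mM * yield_sulfate_per_lactate / yield_sulfide_per_nitrate_total


def minc_from_network(
    lactate_mM: float,
    srb: CommunityReaction,
    nrsob_nitrate_step: CommunityReaction,
    nrsob_nitrite_step: CommunityReaction,
) -> dict[str, float]:
    """The full MINC worked chain from the constructed reactions.

    Returns the sulfate demand of the donor (mM), the direct, indirect and
    total sulfide-per-nitrate yields, and the MINC (mM).
    """
    y_sl = stoich_yield(srb, "sulfate", "lactate")
    direct = stoich_yield(nrsob_nitrate_step, "sulfide", "nitrate")
    indirect = stoich_yield(nrsob_nitrite_step, "sulfide", "nitrite") * stoich_yield(
        nrsob_nitrate_step, "nitrite", "nitrate"
    )
    total = direct + indirect
    return {
        "sulfate_per_lactate": y_sl,
        "sulfate_demand_mM": lactate_mM * y_sl,
        "sulfide_per_nitrate_direct": direct,
        "sulfide_per_nitrate_indirect": indirect,
        "sulfide_per_nitrate_total": total,
        "minc_mM": minc(lactate_mM, y_sl, total),
    }


# ---------------------------------------------------------------------------
# RINC
# ---------------------------------------------------------------------------


class RincSearchError(RuntimeError):
    pass


class ColumnDoseResponse:
    """Quasi-steady sulfide profile as a function of injected nitrate.

    Runs the column to quasi-steady state (relative port/profile change
    below ``steady_rel_tol`` over ``steady_window_days``, or the horizon)
    at constant flow, memoizing runs so bisections at several observation
    distances share simulations.
    """

    def __init__(
        self,
        grid: ColumnGrid,
        network: list[CommunityReaction],
        params: dict[str, KineticParams],
        influent_mM: dict[str, float],
        flow_ml_h: float = 9.0,
        horizon_days: float = 30.0,
        dt_days: float = 0.02,
        inhibition: bool = True,
        rtol: float = 1e-6,
        initial_conc_mM: dict[str, float] | None = None,
        skip_startup: bool = True,
    ):
        self.grid = grid
        self.network = network
        self.params = params
        self.influent = dict(influent_mM)
        self.flow = flow_ml_h
        self.horizon = horizon_days
        self.dt = dt_days
        self.inhibition = inhibition
        self.rtol = rtol
        # default initial state: an established soured column (influent
        # sulfate already fully reduced to sulfide) before dosing begins
        if initial_conc_mM is None:
            initial_conc_mM = {**self.influent, "nitrate": 0.0}
            initial_conc_mM["sulfide"] = initial_conc_mM.get("sulfate", 0.0)
            initial_conc_mM["sulfate"] = 0.0
        self.initial_conc = initial_conc_mM
        self.skip_startup = skip_startup
        self._cache: dict[float, np.ndarray] = {}
        self.has_srb = any(r.name == "SRB" for r in network)

    def sulfide_profile_mM(self, nitrate_mM: float) -> np.ndarray:
        """Quasi-steady sulfide (mM) at every cell centre."""
        key = round(float(nitrate_mM), 9)
        if key in self._cache:
            return self._cache[key]
        influent = {**self.influent, "nitrate": float(nitrate_mM)}
        sched = Schedule([(0.0, self.flow, influent)])
        ports = PortSpec({1: (1,), 2: (self.grid.n_cells,)})
        res = run_column(
            self.grid,
            self.network,
            self.params,
            sched,
            ports=ports,
            initial_conc_mM=self.initial_conc,
            horizon_days=self.horizon,
            dt_days=self.dt,
            sample_every_days=self.horizon,  # ports unused here
            inhibition=self.inhibition,
            rtol=self.rtol,
            skip_startup=self.skip_startup,
        )
        i = res.system.sp_index["sulfide"]
        prof = res.final_state[:, i] * 1e3
        self._cache[key] = prof
        return prof

    def sulfide_at_mM(self, nitrate_mM: float, distance_cm: float) -> float:
        prof = self.sulfide_profile_mM(nitrate_mM)
        return float(np.interp(distance_cm, self.grid.cell_centers_cm, prof))


def rinc_search(
    response: ColumnDoseResponse,
    distance_cm: float,
    sulfide_threshold_mM: float = 0.1,
    bracket_mM: tuple[float, float] = (0.0, 30.0),
    tol_mM: float = 0.25,
) -> float:
    """Bisect for the lowest injected nitrate keeping quasi-steady sulfide
    below the threshold at the observation distance.

    Returns 0 when souring never occurs (e.g. no SRB in the network).
    """
    lo, hi = bracket_mM
    if response.sulfide_at_mM(lo, distance_cm) <= sulfide_threshold_mM:
        return float(lo)
    if response.sulfide_at_mM(hi, distance_cm) > sulfide_threshold_mM:
        raise RincSearchError(
            f"bracket ({lo}, {hi}) mM does not contain the inhibitory dose at {distance_cm} cm"
        )
    while hi - lo > tol_mM:
        mid = 0.5 * (lo + hi)
        if response.sulfide_at_mM(mid, distance_cm) <= sulfide_threshold_mM:
            hi = mid
        else:
            lo = mid
    return float(hi)


# ---------------------------------------------------------------------------
# R ratio
# ---------------------------------------------------------------------------


def r_ratio(
    params: dict[str, KineticParams],
    nitrate_step: CommunityReaction,
    nitrite_step: CommunityReaction,
) -> float:
    """Ratio of maximum specific turnover rates (nitrite step / nitrate step)
    at substrate saturation with the initial biomass."""
    p1, p2 = params[nitrate_step.name], params[nitrite_step.name]
    v1 = p1.mu_max * p1.x0_mol_per_l * abs(nitrate_step.stoich[nitrate_step.acceptor_species])
    v2 = p2.mu_max * p2.x0_mol_per_l * abs(nitrite_step.stoich[nitrite_step.acceptor_species])
    if v1 <= 0:
        raise ValueError("nitrate-step maximum rate is zero; R undefined")
    return v2 / v1


def set_r_ratio(
    params: dict[str, KineticParams],
    nitrate_step: CommunityReaction,
    nitrite_step: CommunityReaction,
    target_R: float,
) -> tuple[dict[str, KineticParams], float]:
    """Rescale the nitrite step's mu_max so the saturation rate ratio equals
    ``target_R``; returns (new params, achieved R)."""
    if target_R <= 0:
        raise ValueError("target_R must be > 0")
    current = r_ratio(params, nitrate_step, nitrite_step)
    out = {k: dc_replace(v) for k, v in params.items()}
    out[nitrite_step.name].mu_max *= target_R / current
    achieved = r_ratio(out, nitrate_step, nitrite_step)
    return out, achieved


def time_to_half_max(series_t: np.ndarray, series_v: np.ndarray) -> float:
    """First time a monotone-ish series reaches half its final maximum."""
    half = 0.5 * np.max(series_v)
    idx = np.flatnonzero(series_v >= half)
    if idx.size == 0:
        return float("inf")
    i = idx[0]
    if i == 0:
        return float(series_t[0])
    t0, t1 = series_t[i - 1], series_t[i]
    v0, v1 = series_v[i - 1], series_v[i]
    return float(t0 + (half - v0) / (v1 - v0) * (t1 - t0))
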