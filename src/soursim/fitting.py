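"""Two-stage global parameter estimation and scenario screening.

Stage one (KPSR) fits the sulfate-reducer kinetics on the sulfate-only batch
experiment; stage two (KPNR) fixes KPSR and fits, per candidate scenario,
the nitrate/nitrite-reducer kinetics plus the SRB nitrite-inhibition
coefficient on the nitrate-amended experiments.  Scenarios are then ranked
by their minimized SSE, with the relative score
``RSSE_i = 100 * (SSE_i - min SSE) / min SSE``.

The global search is an evolutionary (differential evolution) optimizer with
a fixed random seed, followed by a bounded gradient polish (L-BFGS-B).
Rate-type parameters (mu_max, K, I) are searched in log10 space.  A linear
constraint capping the summed initial biomass of all communities is enforced
by proportional repair of candidate X0 vectors before evaluation, so every
evaluated candidate is feasible.

Identifiability notes: with frozen biomass mu_max and X0 enter the dynamics
only through their product, so default problems keep X0 fixed; the nitrite
inhibition coefficient I carries no signal in nitrate-free data and is
therefore estimated in the KPNR stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize

from .batch import (
    DEFAULT_SSE_SPECIES,
    FitScore,
    KineticParams,
    ReactionSystem,
    _range_weight,
    rsse_percent,
)
from .reactions import CommunityReaction, Scenario, build_communities

#: Default bounds per parameter kind (literature-typical ranges; config-
#: overridable).  mu/K/I are searched in log10 space, X0 and b linearly.
DEFAULT_BOUNDS = {
    "mu_max": (1e-6, 1e-3),
    "K_d": (1e-6, 1e-2),
    "K_a": (1e-6, 1e-2),
    "I": (1e-6, 1e-2),
    "b": (0.0, 1e-5),
    "X0": (0.0, 8000.0),
}
LOG_PARAMS = ("mu_max", "K_d", "K_a", "I")

BIOMASS_CAP_MG_L = 8000.0


class ConstraintError(ValueError):
    pass


@dataclass(frozen=True)
class FreeParam:
    community: str
    param: str  # mu_max | K_d | K_a | I | b | X0
    lo: float
    hi: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise ConstraintError(f"bounds lo > hi for {self.community}.{self.param}")

    @property
    def log_scale(self) -> bool:
        return self.param in LOG_PARAMS

    def to_internal(self, value: float) -> float:
        return math.log10(value) if self.log_scale else value

    def from_internal(self, x: float) -> float:
        return 10.0**x if self.log_scale else x

    @property
    def internal_bounds(self) -> tuple[float, float]:
        if self.log_scale:
            return (math.log10(self.lo), math.log10(self.hi))
        return (self.lo, self.hi)


@dataclass
class BatchDesign:
    """The batch experiments to simulate: shared time grid, per-experiment
    initial concentrations (mol/l), keyed by experiment id."""

    t_grid: np.ndarray
    initial_concs: dict[str, dict[str, float]]

    @property
    def ids(self) -> list[str]:
        return list(self.initial_concs)


@dataclass
class FitProblem:
    network: list[CommunityReaction]
    base_params: dict[str, KineticParams]
    free: list[FreeParam]
    design: BatchDesign
    data: pd.DataFrame  # tidy: experiment_id, time_s, species, value (mol/l)
    seed: int = 0
    biomass_cap_mg_l: float = BIOMASS_CAP_MG_L
    sse_species: tuple[str, ...] = DEFAULT_SSE_SPECIES
    inhibition: bool = True
    grow_biomass: bool = False
    rtol: float = 1e-6
    atol: float = 1e-9
    options: dict = field(default_factory=dict)


@dataclass
class FitResult:
    best_params: dict[str, KineticParams]
    sse: float
    score: FitScore
    trace: list[float]
    seed: int
    n_generations: int
    x: np.ndarray


def _apply_candidate(problem: FitProblem, x: np.ndarray) -> dict[str, KineticParams]:
    """Materialize a candidate vector into parameter sets, repairing the
    biomass-sum constraint by proportional down-scaling of free X0 entries."""
    params = {k: dc_replace(v) for k, v in problem.base_params.items()}
    values = [fp.from_internal(xi) for fp, xi in zip(problem.free, x)]
    # constraint repair on X0 before assignment
    fixed_x0 = sum(
        p.X0
        for name, p in params.items()
        if not any(fp.community == name and fp.param == "X0" for fp in problem.free)
    )
    free_x0 = sum(v for fp, v in zip(problem.free, values) if fp.param == "X0")
    budget = problem.biomass_cap_mg_l - fixed_x0
    if free_x0 > budget:
        if budget < 0:
            raise ConstraintError("fixed biomass already exceeds the cap")
        scale = budget / free_x0 if free_x0 > 0 else 0.0
        values = [v * scale if fp.param == "X0" else v for fp, v in zip(problem.free, values)]
    for fp, v in zip(problem.free, values):
        setattr(params[fp.community], fp.param, v)
    return params


class CompiledObjective:
    """The simulate-and-score map of a fit problem, precompiled to arrays.

    Building reaction systems and tidy tables per candidate dominates the
    cost of a population search, so the system is built once and candidate
    parameter sets are written into its kinetic arrays in place; the scoring
    loop runs on pre-grouped numpy arrays.
    """

    def __init__(self, problem: FitProblem):
        self.problem = problem
        self.system = ReactionSystem(
            problem.network,
            problem.base_params,
            inhibition=problem.inhibition,
            grow_biomass=problem.grow_biomass,
        )
        design = problem.design
        self.t_grid = np.asarray(design.t_grid, dtype=float)
        exp_index = {e: k for k, e in enumerate(design.ids)}
        sysm = self.system
        self.conc0 = np.zeros((len(design.ids), sysm.n_state))
        for e, k in exp_index.items():
            for sp, v in design.initial_concs[e].items():
                if sp in sysm.sp_index:
                    self.conc0[k, sysm.sp_index[sp]] = v
        data = problem.data[problem.data["species"].isin(problem.sse_species)]
        if data.empty:
            raise ValueError("no observations for the scored species")
        weights = {sp: _range_weight(g["value"]) for sp, g in data.groupby("species")}
        self.groups: list[tuple[int, int | None, np.ndarray, np.ndarray, float]] = []
        for (exp_id, sp), g in data.groupby(["experiment_id", "species"]):
            self.groups.append(
                (
                    exp_index[exp_id],
                    sysm.sp_index.get(sp),
                    g["time_s"].to_numpy(dtype=float),
                    g["value"].to_numpy(dtype=float),
                    weights[sp],
                )
            )

    def _install(self, params: dict[str, KineticParams]):
        sysm = self.system
        for j, rxn in enumerate(sysm.network):
            p = params[rxn.name]
            sysm.mu[j] = p.mu_max
            sysm.Kd[j] = p.K_d
            sysm.Ka[j] = p.K_a
            sysm.b[j] = p.b
            if sysm.inhib_idx[j] >= 0:
                sysm.I[j] = p.I if p.I is not None else np.inf
            self.conc0[:, sysm.n_dyn + j] = p.x0_mol_per_l

    def score(self, params: dict[str, KineticParams]) -> FitScore:
        self._install(params)
        out = self.system.integrate_capped(
            self.conc0.ravel(),
            self.t_grid,
            rtol=self.problem.rtol,
            atol=self.problem.atol,
            mxstep=self.problem.options.get("mxstep", 3000),
        )
        out = out.reshape(len(self.t_grid), self.conc0.shape[0], self.system.n_state)
        total = 0.0
        per_species: dict[str, float] = {}
        for k, si, times, values, w in self.groups:
            model = np.zeros_like(values) if si is None else np.interp(times, self.t_grid, out[:, k, si])
            res = (model - values) / w
            contrib = float(res @ res)
            total += contrib
            name = self.system.species[si] if si is not None else "absent"
            per_species[name] = per_species.get(name, 0.0) + contrib
        return FitScore(sse=total, per_species_sse=per_species)


def evaluate(problem: FitProblem, params: dict[str, KineticParams]) -> FitScore:
    return CompiledObjective(problem).score(params)


def fit(problem: FitProblem) -> FitResult:
    """Seeded evolutionary global search with optional local polish."""
    opts = {
        "maxiter": 40,
        "popsize": 6,
        "tol": 1e-8,
        "mutation": (0.5, 1.0),
        "recombination": 0.7,
        "polish": True,
        "polish_maxiter": 40,
        "polish_maxfun": 1000,
        **problem.options,
    }
    bounds = [fp.internal_bounds for fp in problem.free]
    compiled = CompiledObjective(problem)

    best_seen = {"f": np.inf, "x": None}

    def objective(x):
        try:
            params = _apply_candidate(problem, x)
            f = compiled.score(params).sse
        except Exception:
            f = 1e12
        if f < best_seen["f"]:
            best_seen["f"] = f
            best_seen["x"] = np.array(x)
        return f

    trace: list[float] = []

    if opts["maxiter"] <= 0:
        # degenerate budget: evaluate the seeded initial population only
        rng = np.random.default_rng(problem.seed)
        n = max(5, opts["popsize"] * len(bounds))
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        pop = lo + rng.random((n, len(bounds))) * (hi - lo)
        for cand in pop:
            objective(cand)
        x_best = best_seen["x"]
        n_gen = 0
    else:
        res = differential_evolution(
            objective,
            bounds,
            seed=problem.seed,
            maxiter=opts["maxiter"],
            popsize=opts["popsize"],
            tol=opts["tol"],
            mutation=opts["mutation"],
            recombination=opts["recombination"],
            polish=False,
            init="latinhypercube",
            callback=lambda xk, convergence=0.0: trace.append(best_seen["f"]) or False,
        )
        n_gen = res.nit
        if opts["polish"]:
            minimize(
                objective,
                best_seen["x"],
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": opts["polish_maxiter"], "maxfun": opts["polish_maxfun"]},
            )
        x_best = best_seen["x"]  # tracks every evaluation, incl. the polish

    params = _apply_candidate(problem, x_best)
    score = compiled.score(params)
    trace.append(min(best_seen["f"], score.sse))
    # enforce a non-increasing reported trace (best-so-far semantics)
    trace = list(np.minimum.accumulate(trace)) if trace else [score.sse]
    return FitResult(
        best_params=params,
        sse=score.sse,
        score=score,
        trace=trace,
        seed=problem.seed,
        n_generations=n_gen,
        x=np.asarray(x_best, dtype=float),
    )


# ---------------------------------------------------------------------------
# Stage wrappers
# ---------------------------------------------------------------------------


def default_free_params(
    communities: list[str],
    bounds: dict[str, tuple[float, float]] | None = None,
    include_inhibition: bool = True,
    free_x0: bool = False,
) -> list[FreeParam]:
    """(mu_max, K_d, K_a) per nitrogen-cycle community (+ SRB's I)."""
    b = {**DEFAULT_BOUNDS, **(bounds or {})}
    free: list[FreeParam] = []
    for name in communities:
        if name == "SRB":
            continue
        for p in ("mu_max", "K_d", "K_a"):
            free.append(FreeParam(name, p, *b[p]))
        if free_x0:
            free.append(FreeParam(name, "X0", *b["X0"]))
    if include_inhibition and "SRB" in communities:
        free.append(FreeParam("SRB", "I", *b["I"]))
    return free


def fit_kpsr(
    srb: CommunityReaction,
    srb_params: KineticParams,
    design: BatchDesign,
    data: pd.DataFrame,
    seed: int = 0,
    bounds: dict[str, tuple[float, float]] | None = None,
    options: dict | None = None,
) -> FitResult:
    """Fit SRB kinetics (mu_max, K_d, K_a) on sulfate-only data.

    The data must carry no nitrate/nitrite signal; the inhibition
    coefficient is left to the KPNR stage where nitrite is present.
    """
    if not data[data["species"].isin(["nitrate", "nitrite"])].query("value > 0").empty:
        raise ValueError("KPSR data must contain no nitrate/nitrite signal")
    b = {**DEFAULT_BOUNDS, **(bounds or {})}
    free = [FreeParam("SRB", p, *b[p]) for p in ("mu_max", "K_d", "K_a")]
    problem = FitProblem(
        network=[srb],
        base_params={"SRB": srb_params},
        free=free,
        design=design,
        data=data,
        seed=seed,
        sse_species=("sulfate", "sulfide"),
        inhibition=False,
        options=options or {},
    )
    return fit(problem)


def scenario_problem(
    scenario: Scenario,
    kpsr_fixed: KineticParams,
    design: BatchDesign,
    data: pd.DataFrame,
    seed: int = 0,
    x0_values: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    options: dict | None = None,
    communities: dict[str, CommunityReaction] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> FitProblem:
    """Build the KPNR fit problem for one scenario with KPSR held fixed.

    By default each community's initial biomass X0 is a free parameter under
    the summed biomass cap, mirroring the constrained experimental inoculum.
    Passing ``x0_values`` instead fixes the inoculum composition (mg/l) and
    removes X0 from the search — the choice for parameter-recovery studies,
    since with frozen biomass only the product mu_max * X0 is identifiable.
    """
    comms = communities or build_communities()
    names = scenario.communities()
    network = [comms[n] for n in names]
    budget = BIOMASS_CAP_MG_L - kpsr_fixed.X0
    n_nr = len(names) - 1
    base = {"SRB": dc_replace(kpsr_fixed, I=kpsr_fixed.I or 1e-4)}
    for n in names[1:]:
        x0 = (x0_values or {}).get(n, budget / n_nr)
        base[n] = KineticParams(1e-5, 1e-4, 1e-4, X0=x0)
    b = {**DEFAULT_BOUNDS, **(bounds or {})}
    free = default_free_params(
        names,
        bounds={**b, "X0": (0.0, budget)},
        include_inhibition=True,
        free_x0=x0_values is None,
    )
    return FitProblem(
        network=network,
        base_params=base,
        free=free,
        design=design,
        data=data,
        seed=seed,
        rtol=rtol,
        atol=atol,
        options=options or {},
    )


def fit_kpnr(
    scenario: Scenario,
    kpsr_fixed: KineticParams,
    design: BatchDesign,
    data: pd.DataFrame,
    seed: int = 0,
    **kwargs,
) -> FitResult:
    """Global + local KPNR fit of one admissible scenario."""
    if not scenario.admissible:
        raise ValueError(f"scenario {scenario.label} is not admissible")
    return fit(scenario_problem(scenario, kpsr_fixed, design, data, seed=seed, **kwargs))


def screen_scenarios(
    scenarios: list[Scenario],
    kpsr_fixed: KineticParams,
    design: BatchDesign,
    data: pd.DataFrame,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Fit every scenario and rank by SSE (ascending, stable canonical order).

    Returns a table (scenario, sse, rsse_percent, n_params, result).  Each
    scenario's search is seeded deterministically from ``seed`` and its
    position in the canonical enumeration.
    """
    if not scenarios:
        raise ValueError("no scenarios to screen")
    rows = []
    options = dict(kwargs.pop("options", {}) or {})
    pop_total = options.pop("pop_total", None)
    for i, sc in enumerate(scenarios):
        sc_options = dict(options)
        if pop_total is not None:
            # equalize the *total* population across scenario sizes, so small
            # scenarios are not out-searched by large ones
            n_params = 4 * (len(sc.communities()) - 1) + 1
            sc_options["popsize"] = max(2, math.ceil(pop_total / n_params))
        res = fit_kpnr(sc, kpsr_fixed, design, data, seed=seed + i, options=sc_options, **kwargs)
        rows.append({"scenario": sc.label, "sse": res.sse, "n_params": len(res.x), "result": res})
    table = pd.DataFrame(rows)
    table["rsse_percent"] = rsse_percent(table["sse"].tolist())
    table = table.sort_values(["sse", "scenario"], kind="stable").reset_index(drop=True)
    return table[["scenario", "sse", "rsse_percent", "n_params", "result"]]
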