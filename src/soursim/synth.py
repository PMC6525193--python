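"""Synthetic batch and column datasets from known ground truth.

The generator emulates the two calibration designs the modelling pipeline is
built around: (i) five well-mixed batch experiments at initial sulfate
1000 mg/l, lactate 2500 mg/l and nitrate 0/200/500/700/1000 mg/l with a
heavy 8000 mg/l inoculum observed over a 0-12 h grid; and (ii) a 4.5 cm x
64 cm up-flow sand column with sampling ports whose first/last ports are
read at cells (6,7) and (62,63).  Trajectories are computed from a stated
ground-truth parameter set and observed through a simple measurement model:
multiplicative Gaussian noise (default sigma = 5%) with an absolute floor of
0.5 mg/l per species, truncated at zero.  Noise perturbs observations only;
the noiseless channel is retained, and regeneration under a fixed seed is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .batch import KineticParams, ReactionSystem, simulate_experiments
from .chem import mg_per_l_to_mol_per_l, species
from .fitting import BatchDesign
from .reactions import CommunityReaction, Scenario, build_communities, is_admissible

OBSERVED_SPECIES = ("lactate", "sulfate", "sulfide", "nitrate", "nitrite", "ammonium")

#: The batch design: initial concentrations in mg/l except ammonium, which is
#: a 5 mM medium amendment (cells need an N source; the nitrate-free control
#: could not grow otherwise).
BATCH_NITRATE_MG_L = (0.0, 200.0, 500.0, 700.0, 1000.0)
BATCH_SULFATE_MG_L = 1000.0
BATCH_LACTATE_MG_L = 2500.0
BATCH_AMMONIUM_MOL_L = 5e-3
BATCH_HORIZON_H = 12.0

NOISE_SIGMA = 0.05
NOISE_FLOOR_MG_L = 0.5


@dataclass
class GroundTruth:
    """A scenario label plus the full kinetic parameter set behind a dataset."""

    scenario: Scenario
    params: dict[str, KineticParams]


def default_batch_truth() -> GroundTruth:
    """Fixture truth: scenario A (heterotrophic DNRA) plus SRB.

    Rates are chosen so the five experiments show the canonical phenomen-
    ology within 12 h: full nitrate reduction with transient nitrite
    accumulation, strong nitrite inhibition of SRB (I = 0.1 mM), and sulfate
    drawdown in the nitrate-free control.
    """
    return GroundTruth(
        scenario=Scenario(groups=("A",)),
        params={
            "SRB": KineticParams(2.0e-6, 1e-4, 2e-4, I=1e-4, b=0.0, X0=2000.0),
            "NRB1": KineticParams(2.0e-6, 1e-4, 2e-4, X0=1000.0),
            "NRB2": KineticParams(1.5e-6, 1e-4, 2e-4, X0=1000.0),
        },
    )


def default_column_truth() -> GroundTruth:
    """Fixture truth for the flow design: SRB plus group B (autotrophic DNRA
    by nitrate-reducing sulfide oxidizers), growing biomass."""
    return GroundTruth(
        scenario=Scenario(groups=("B",)),
        params={
            "SRB": KineticParams(2.0e-5, 1e-4, 1e-4, I=1e-4, b=1e-6, X0=10.0),
            "NRSOB1": KineticParams(2.0e-5, 1e-4, 1e-4, b=1e-6, X0=10.0),
            "NRSOB2": KineticParams(2.0e-5, 1e-4, 1e-4, b=1e-6, X0=10.0),
        },
    )


def mechanism_column_truth() -> GroundTruth:
    """Fixture truth for the nitrate-dose / path-length analyses.

    Chosen so the 2 m column sits in the *titration* regime: sulfate
    reduction, sulfide oxidation and nitrite reduction are all fast relative
    to transport, so the point where the injected nitrogen is exhausted (and
    souring resumes) moves downstream with the dose.  Inhibition is moderate
    (I = 0.2 mM) so SRB remain partly active under nitrite and keep feeding
    the sulfur cycle that consumes the oxidant.
    """
    return GroundTruth(
        scenario=Scenario(groups=("B",)),
        params={
            "SRB": KineticParams(1e-5, 1e-4, 1e-4, I=2e-4, b=2e-6, X0=200.0),
            "NRSOB1": KineticParams(4e-6, 1e-4, 2e-4, b=2e-6, X0=200.0),
            "NRSOB2": KineticParams(4e-6, 1e-4, 2e-4, b=2e-6, X0=200.0),
        },
    )


#: Influent of the dose/path-length fixture (mM).
MECHANISM_INFLUENT_MM = {"sulfate": 10.0, "lactate": 25.0, "ammonium": 1.0}


@dataclass
class SyntheticDataset:
    design: str  # "batch" | "column"
    truth: GroundTruth
    seed: int
    noise_sigma: float
    observations: pd.DataFrame  # tidy: experiment_id/port, time, species, value
    noiseless: pd.DataFrame
    batch_design: BatchDesign | None = None
    extras: dict = field(default_factory=dict)


def _apply_noise(values: np.ndarray, names: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Gaussian noise with an absolute mg/l floor, truncated at 0."""
    floor = np.array([mg_per_l_to_mol_per_l(NOISE_FLOOR_MG_L, n) for n in names])
    sd = np.sqrt((sigma * values) ** 2 + floor**2)
    return np.maximum(values + sd * rng.standard_normal(values.shape), 0.0)


def batch_design(
    nitrate_mg_l: tuple[float, ...] = BATCH_NITRATE_MG_L,
    n_times: int = 13,
    horizon_h: float = BATCH_HORIZON_H,
) -> BatchDesign:
    t_grid = np.linspace(0.0, horizon_h * 3600.0, n_times)
    concs = {}
    for n in nitrate_mg_l:
        concs[f"NO3_{int(n)}"] = {
            "sulfate": mg_per_l_to_mol_per_l(BATCH_SULFATE_MG_L, "sulfate"),
            "lactate": mg_per_l_to_mol_per_l(BATCH_LACTATE_MG_L, "lactate"),
            "nitrate": mg_per_l_to_mol_per_l(n, "nitrate"),
            "ammonium": BATCH_AMMONIUM_MOL_L,
        }
    return BatchDesign(t_grid=t_grid, initial_concs=concs)


def make_batch_set(
    truth: GroundTruth | None = None,
    noise_sigma: float = NOISE_SIGMA,
    seed: int = 0,
    design: BatchDesign | None = None,
    communities: dict[str, CommunityReaction] | None = None,
) -> SyntheticDataset:
    """Generate the five-experiment batch dataset from a ground truth."""
    truth = truth or default_batch_truth()
    if not is_admissible(truth.scenario.groups):
        raise ValueError(f"inadmissible truth scenario {truth.scenario.groups}")
    design = design or batch_design()
    comms = communities or build_communities()
    network = [comms[n] for n in truth.scenario.communities()]
    system = ReactionSystem(network, truth.params, grow_biomass=False)
    out = simulate_experiments(
        system, [design.initial_concs[i] for i in design.ids], design.t_grid
    )
    rows = []
    for k, exp_id in enumerate(design.ids):
        for si, sp in enumerate(system.species):
            if sp not in OBSERVED_SPECIES:
                continue
            for ti, t in enumerate(design.t_grid):
                rows.append((exp_id, float(t), sp, float(out[k, ti, si])))
    noiseless = pd.DataFrame(rows, columns=["experiment_id", "time_s", "species", "value"])
    rng = np.random.default_rng(seed)
    obs = noiseless.copy()
    if noise_sigma > 0:
        obs["value"] = _apply_noise(
            obs["value"].to_numpy(), obs["species"].to_numpy(), noise_sigma, rng
        )
    return SyntheticDataset(
        design="batch",
        truth=truth,
        seed=seed,
        noise_sigma=noise_sigma,
        observations=obs,
        noiseless=noiseless,
        batch_design=design,
    )


def make_column_set(
    truth: GroundTruth | None = None,
    schedule=None,
    noise_sigma: float = NOISE_SIGMA,
    seed: int = 0,
    grid=None,
    **run_kwargs,
) -> SyntheticDataset:
    """Generate noisy port time-series from a column-model ground truth.

    Heavy lifting is delegated to :func:`soursim.column.run_column`; the
    noiseless port series is retained alongside the noisy observations.
    """
    from .column import ColumnGrid, default_flow_schedule, run_column

    truth = truth or default_column_truth()
    if not is_admissible(truth.scenario.groups):
        raise ValueError(f"inadmissible truth scenario {truth.scenario.groups}")
    grid = grid or ColumnGrid()
    schedule = schedule if schedule is not None else default_flow_schedule()
    comms = build_communities()
    network = [comms[n] for n in truth.scenario.communities()]
    result = run_column(grid, network, truth.params, schedule, **run_kwargs)
    noiseless = result.port_series.rename(columns={"value_mM": "value"}).copy()
    noiseless["value"] *= 1e-3  # mM -> mol/l, matching the batch schema
    rng = np.random.default_rng(seed)
    obs = noiseless.copy()
    if noise_sigma > 0:
        obs["value"] = _apply_noise(
            obs["value"].to_numpy(), obs["species"].to_numpy(), noise_sigma, rng
        )
    return SyntheticDataset(
        design="column",
        truth=truth,
        seed=seed,
        noise_sigma=noise_sigma,
        observations=obs,
        noiseless=noiseless,
        extras={"result": result},
    )
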