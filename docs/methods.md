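# Methods

This note documents the models implemented in `soursim`, the choices made
where the design was genuinely open, and what the packaged synthetic
fixtures do and do not demonstrate.

## Reaction network construction

Every microbial community is represented by one overall growth reaction
assembled from three half-reactions written per electron equivalent
(e-eq): an electron-donor half-reaction, an electron-acceptor
half-reaction, and a cell-synthesis half-reaction producing biomass
C5H7O2N with ammonium as nitrogen source (20 e-eq/mol biomass).  A
fraction `fe` of the donor's electrons goes to the acceptor (energy) and
`fs = 1 − fe` to synthesis; the summed stoichiometry is renormalized to
1 mol biomass.  Because each half-reaction is individually element- and
charge-balanced per electron, the overall reaction balances by
construction (checked to 1e-8 everywhere).

Half-reaction inventory (e-eq per mole of the reference species): lactate
full oxidation 12; sulfate→H2S 8; NO3⁻→NO2⁻ 2; NO2⁻→NH4⁺ 6 (DNRA arm);
NO2⁻→½N2 3 (denitrification arm, lumped — no NO/N2O intermediates);
HS⁻→SO4²⁻ 8; HS⁻→S⁰ 2; S⁰→SO4²⁻ 6.  Energy fractions are pinned to
`fe(SRB) = 0.8499`, `fe(NRSOB1) = 0.8623`, `fe(NRSOB2) = 0.8656` (all
other communities 0.86, overridable in config).  These values make the
stoichiometric chain come out at the canonical figures for this system:
12·0.8499/8 = 1.2748 mol sulfate per mol lactate for the sulfate
reducers, 0.25/0.8623 = 0.2899 mol sulfide oxidized per mol nitrate
directly, and 0.75/0.8656 = 0.8665 via the nitrite produced (1 mol
nitrite per mol nitrate — ammonium, not nitrate, is the N source for
synthesis), 1.156 in total.

Ten nitrogen-cycle communities plus one SRB community are predefined.
They pair into groups A–F (a nitrate step and a nitrite step sharing one
donor): A — heterotrophic DNRA; B — autotrophic DNRA with sulfide→sulfate;
C — sulfide→S⁰; D — S⁰→sulfate; E — heterotrophic denitrification; F —
autotrophic denitrification.  Admissible scenarios are non-empty group
sets within one pathway family, with D admitted only alongside C (its S⁰
substrate source): 11 DNRA + 3 denitrification = 14.

## Kinetics

Each community grows at

    r = μmax · X · C_d/(C_d+K_d) · C_a/(C_a+K_a) · I/(C_inh+I) − b·X

with the product-inhibition factor present only for SRB (nitrite).
Species turnover is stoichiometric per mole of biomass synthesized and is
driven by the gross growth term; decay `b·X` removes biomass only (the
mass fate of decayed biomass is not modelled).  Batch simulations default
to frozen biomass — the calibration design inoculates 8000 mg/l so net
growth over ≤12 h is negligible while substrate turnover is not — with a
switch for growth; the column model always grows biomass.

Non-negativity is enforced smoothly: each reaction is multiplied by
s(C) = C₊²/(C²+δ²), δ = 1e-12 mol/l, for every species it consumes, which
keeps the right-hand side Lipschitz instead of hard-clipping states.
Water, protons and CO2 are treated as buffered (no pH or carbonate
chemistry).  The stiff systems are integrated with LSODA and a banded
Jacobian (stacked independent reactors are block-diagonal); a
numba-compiled kernel evaluates the rate law, with an equivalent numpy
fallback, and the two are asserted equal in the tests.

## Fitting and scenario screening

Stage 1 (KPSR) fits the SRB parameters (μmax, K_d, K_a) on the
nitrate-free experiment; stage 2 (KPNR) fixes KPSR and fits each
scenario's nitrogen-cycle communities plus the SRB inhibition coefficient
I (which carries no signal in nitrate-free data).  The global search is
`scipy.optimize.differential_evolution` with a fixed seed, followed by a
bounded L-BFGS-B polish; μmax, K and I are searched in log10 space.
Default bounds: μmax ∈ [1e-6, 1e-3] s⁻¹, K ∈ [1e-6, 1e-2] mol/l,
I ∈ [1e-6, 1e-2] mol/l, b ∈ [0, 1e-5] s⁻¹, X0 ∈ [0, 8000] mg/l.  Inside
the fitting loop a work-capped LSODA (`odeint` with `mxstep`) rejects
pathological candidates quickly instead of stalling the population.

The summed initial biomass of all communities is capped at 8000 mg/l (the
experimental inoculum).  The cap is enforced by proportional repair of
candidate X0 vectors before evaluation, so every evaluated candidate is
feasible and fitness values remain comparable across scenarios.  In
scenario screening X0 is free under this cap; in parameter-recovery
studies X0 is fixed at the known inoculum split, because with frozen
biomass only the product μmax·X0 is identifiable.  Two further
identifiability facts shape the defaults: the donor half-saturation K_d
is weakly identified when lactate (2500 mg/l ≈ 28 mM) never approaches
K_d, so recovery claims are made for μmax and the acceptor K_a; and the
fitted SSE uses sulfate, sulfide, nitrate, nitrite *and ammonium* —
lactate is excluded (its decay in the calibration experiments is partly
fermentative, which the network deliberately does not model), while
ammonium is included because it is the only observable separating the
DNRA nitrite step (NO2⁻→NH4⁺) from the denitrification step (NO2⁻→½N2):
without it the two pathway families are mutually indistinguishable on
range-normalized residuals.

Residuals are normalized per species by the observed range (floored at 5%
of the species' magnitude so constant channels keep a finite weight).
Scenario ranking uses RSSE_i = 100·(SSE_i − min SSE)/min SSE, ascending,
with ties broken by the canonical scenario order.

## Column model

The packed bed (4.5 cm diameter × 64 cm, 225 µm sand) is a 1D
finite-volume grid of 64 one-centimetre cells (centres at (i−0.5) cm,
1-based indices).  Transport is explicit upwind advection plus central
dispersion in flux form (mass-conservative to round-off), sub-cycled to
the explicit stability limit; the inlet is an advective flux boundary at
the influent composition and the outlet advective with zero dispersive
gradient.  Biomass and elemental sulfur are immobile.  Porosity defaults
to 0.375 (typical for a random pack of this sand, and consistent with the
observed ~1.55-day advective travel time between the first and last
sampling ports at 9 ml/h); dispersion is D = D_m + α·v with
D_m = 1e-9 m²/s and α = 0.1 cm (not reported for the original column; a
sensitivity test covers the choice).

Operator splitting is sequential transport-then-reaction per global step
(default 0.01–0.04 d in the packaged runs; a Strang option exists).  The
reaction operator integrates all cells as one block-diagonal stacked
system through the same solver as the batch model, so a single-cell
reaction step reproduces the batch simulation to solver tolerance — this
equivalence, global per-species mass-balance closure (<1e-6 relative),
splitting convergence (<0.5% on halving dt) and grid convergence (<2% on
doubling cells) are all asserted in the test suite.

The experimental protocol is mimicked in two phases: a no-flow startup
integrated until the minimum sulfate over the column reaches 0.1 mM
("complete" = 99% reduction), then the scheduled flow/influent program.
The shipped long-run schedule (flow ramp 0.5→9 ml/h at +0.5 ml/h per day;
nitrate steps 2.5/5/10/15/17.5/20 mM at days 21/40/60/86/100/110;
lactate 25 mM) is an editable reconstruction of the original program from
its narrative description, not a measured table; all quantitative tests
use synthetic fixtures instead.  Ports 1 and 5 are the averages of cells
(6,7) and (62,63).  Because the influent sulfate of the original
experiment is known only through mass balance, `estimate_influent_sulfate`
averages sulfate+sulfide over consecutive samples, exactly the procedure
a practitioner would apply to the real series.

## Mechanism dissection and design metrics

Variant runs toggle single mechanisms: the full model; the model with the
nitrite-inhibition factor removed; and the model with all nitrate
reducers removed (SRB only).  Comparing their SSE against souring data
separates nitrite inhibition from biocompetition and sulfur cycling.

MINC (minimum inhibitory nitrate concentration) is pure stoichiometry:
`MINC = lactate · Y(sulfate/lactate) / Y(sulfide/nitrate, total)`; the
worked chain for 25 mM lactate gives 25·1.2748 = 31.87 mM sulfate demand
and 31.87/1.156 = 27.56 mM nitrate.  RINC (required inhibitory nitrate
concentration) is dynamic: the lowest injected nitrate keeping
quasi-steady sulfide below a threshold at an observation distance, found
by bisection over memoized column runs.  The "inhibited" threshold is
0.1 mM sulfide (config-exposed; no standard numeric criterion exists) and
quasi-steady means <1% relative change over 5 simulated days or the run
horizon.  R is the ratio of maximum specific turnover rates of the
nitrite step to the nitrate step at substrate saturation with initial
biomass, manipulated by rescaling the nitrite step's μmax only.

## Synthetic fixtures

The batch generator reproduces the five-experiment calibration design:
sulfate 1000 mg/l, lactate 2500 mg/l, nitrate 0/200/500/700/1000 mg/l,
8000 mg/l total inoculum, observations on a 13-point grid over 0–12 h,
plus a 5 mM ammonium medium amendment (an N source is required for any
growth reaction; the nitrate-free control would otherwise be inert).
Measurement noise is multiplicative Gaussian (σ = 5%) with an absolute
floor of 0.5 mg/l per species, truncated at zero — a realistic scale for
ion-chromatography data; noise is applied to observations only and the
noiseless channel is kept.  The default batch truth is scenario A
(heterotrophic DNRA) with rates (μmax ≈ 2e-6 s⁻¹ at the inoculum scale)
chosen so all five experiments show the canonical phenomenology inside
the 12 h window: complete nitrate drawdown, transient nitrite
accumulation that suppresses SRB (I = 0.1 mM), ammonium production, and
sulfate reduction in the control.

The column truth is SRB plus group B (autotrophic DNRA), matching the
community identified in the flow experiment.  The dose/path-length
analyses use a separate fixture (`mechanism_column_truth`) representing an
established soured column: it sits in the *titration* regime where
sulfate reduction, sulfide oxidation and nitrite reduction are all fast
relative to transport, so the point at which the injected nitrogen is
exhausted — and souring resumes — moves downstream with the dose.  This is
the regime in which the required dose depends on path length; outside it
(very strong inhibition or very slow nitrite turnover) RINC becomes
distance-flat because a trace of surviving nitrite suppresses SRB
everywhere.

What passing the fixture tests shows — and does not.  They demonstrate
that the pipeline recovers known kinetics from its own forward model,
ranks the generating pathway first among all 14 scenarios, and reproduces
the qualitative mechanism orderings (inhibition-off ≈ SRB-only ≫ full
model; sulfide non-increasing in dose; RINC non-decreasing in distance;
souring delayed as R falls).  They do not calibrate real measurements:
the original batch and flow series exist only as published figures, and
the fitted parameter tables of the source study are not reproduced here.

## Problem sizes and numerical settings in the packaged runs

Screening fits all 14 scenarios at a reduced evolutionary budget
(population ≈ 2–3 per parameter, ≤ 10–20 generations, capped polish);
recovery fits use a deeper budget (tolerance 1e-10, polish to
convergence).  Column analyses use the 64-cell grid (or 40 × 5 cm cells
for the 2 m variant), splitting steps of 0.02–0.04 d and 10–12 day
horizons from a pre-soured initial state.  Fitting-stage integrations run
at rtol 1e-4–1e-5; reported simulations at rtol 1e-6–1e-8.  All random
draws (noise, optimizer) flow from explicit integer seeds recorded in
results and manifests.

## Known limitations

Lactate fermentation, pH/speciation, temperature dependence, lag phases,
permeability change by biomass, and 2D/heterogeneous domains are out of
scope.  Decay returns no substrate.  The denitrification arm is lumped to
N2.  Elemental sulfur is a single shared immobile pool.  The original
calibration measurements exist only as published figures and their fitted
parameter tables are not redistributed here; the half-reactions are
standard electron-equivalent constructions pinned to the canonical
yields, and comparisons against the original fitted curves are
qualitative.
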