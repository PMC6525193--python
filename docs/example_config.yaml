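# Example soursim run configuration (schema version 1).
#
# Every block is optional; omitted values fall back to the documented
# defaults.  Kinetic units: mu_max and b in 1/s, K_d/K_a/I in mol/l,
# X0 in mg/l.

schema_version: 1
seed: 42
units: mM

# Energy electron fractions of the bioenergetic construction; only
# overrides need to be listed.
fe_overrides:
  SRB: 0.8499

kinetics:
  SRB:    {mu_max: 2.0e-06, K_d: 1.0e-04, K_a: 2.0e-04, I: 1.0e-04, b: 0.0, X0: 2000.0}
  NRB1:   {mu_max: 2.0e-06, K_d: 1.0e-04, K_a: 2.0e-04, X0: 1000.0}
  NRB2:   {mu_max: 1.5e-06, K_d: 1.0e-04, K_a: 2.0e-04, X0: 1000.0}

grid:
  length_cm: 64.0
  n_cells: 64
  diameter_cm: 4.5
  porosity: 0.375
  dispersivity_cm: 0.1

# Piecewise-constant [t_start_days, flow_ml_h, influent mM] steps.
schedule:
  - [0.0, 9.0, {sulfate: 10.0, lactate: 25.0, ammonium: 1.0}]
  - [10.0, 9.0, {sulfate: 10.0, lactate: 25.0, ammonium: 1.0, nitrate: 10.0}]

fitting:
  options: {maxiter: 20, popsize: 4}

# Keyword arguments forwarded to the column runner by `simulate-column`.
mechanism:
  run: {horizon_days: 3.0, dt_days: 0.05, sample_every_days: 0.25}
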