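# Steady-state parameter-derivation assumptions.
#
# The cluster steady state gives one balance equation per model variable;
# these assumptions close the system so every rate is uniquely determined:
#   fixed_rates  -- decay / turnover rates taken as known (per day)
#   shares       -- nonnegative weights, summing to 1 within each flux group,
#                   that apportion a steady-state flux among its terms
#   alpha_NC     -- fraction of dying cancer cells that become necrotic
#
# These are placeholder values (uniform shares, unit turnover); edit this
# file, not code, to supply literature-derived rates.  Per-cluster overrides
# go under `clusters:`.
version: 1
fixed_rates:
  delta_H: 1.0
  delta_mu1: 1.0
  delta_mu2: 1.0
  delta_Ig: 1.0
  delta_Gb: 1.0
  delta_TN: 1.0
  delta_M: 1.0
  turnover_Th: 1.0
  turnover_TC: 1.0
  turnover_Tr: 1.0
  turnover_D: 1.0
  turnover_C: 1.0
alpha_NC: 0.5
shares:
  H_production: {N: 0.2, M: 0.2, Th: 0.2, TC: 0.2, Tr: 0.2}
  mu1_production: {Th: 0.334, M: 0.333, D: 0.333}
  mu2_production: {M: 0.334, D: 0.333, Tr: 0.333}
  Ig_production: {Th: 0.334, TC: 0.333, M: 0.333}
  Gb_production: {M: 0.5, Tr: 0.5}
  Th_activation: {D: 0.334, M: 0.333, mu1: 0.333}
  Th_loss: {mu2: 0.334, Tr: 0.333, natural: 0.333}
  TC_activation: {Th: 0.5, D: 0.5}
  TC_loss: {mu2: 0.334, Tr: 0.333, natural: 0.333}
  Tr_activation: {Th: 0.334, mu2: 0.333, Gb: 0.333}
  Tr_loss: {mu1: 0.5, natural: 0.5}
  D_activation: {H: 0.5, C: 0.5}
  D_loss: {H: 0.334, C: 0.333, natural: 0.333}
  M_activation: {mu2: 0.334, Ig: 0.333, Th: 0.333}
  C_production: {base: 0.5, mu1: 0.5}
  C_loss: {Gb: 0.25, Ig: 0.25, TC: 0.25, natural: 0.25}
clusters: {}
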