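# Methods

## Model structure

The state is the 14-vector (T_N, T_h, T_C, T_r, D_N, D, M, C, N, H, μ1, μ2,
Iγ, Gβ): nine cell densities in cells/cm³ and five cytokine levels in
cohort-fixed expression units (deconvolution pipelines report RNA-seq-scale
quantities; no absolute cytokine unit is defined, and none is needed because
the analysis runs on the rescaled system).  All interactions are mass
action.  Cytokines are produced linearly by their source cells and decay
linearly.  T-cell activation terms multiply the naive T-cell density T_N,
which both bounds the activated pools and drains T_N; the same pattern
links naive and activated dendritic cells, where HMGB1 and cancer-derived
signals activate D_N and HMGB1 and cancer also contribute to dendritic
death.  The two dendritic equations share the HMGB1-driven and natural
death rates (δ_DH, δ_D): the loss written for the naive pool reads
(δ_DH·H + δ_D)·D_N, the same symbols the activated equation carries, and we
treat them as one rate each.  The total macrophage pool M0 = M_N + M is
conserved (its influx A_M = δ_M·M0 is never simulated; naive macrophages
are reported as M0 − M), so activation terms carry the factor (M0 − M),
which also caps M at M0 for any initial M ≤ M0.  Cancer follows logistic
growth with capacity C0 and a proliferation rate boosted by the
carcinogenic pool μ1; its death rate collects TGF-β, IFN-γ, cytotoxic-cell
and baseline contributions.  Necrotic production is α_NC times the whole
cancer death flux — the bracket multiplying C in the cancer equation — and
necrotic cells decay at δ_N.

State ordering is fixed everywhere (vectors, matrices, CSV columns):
T_N, T_h, T_C, T_r, D_N, D, M, C, N, H, μ1, μ2, Iγ, Gβ.

## Parameter estimation by steady-state balances

Each cluster supplies one steady-state value per variable.  Setting every
derivative to zero gives 14 balance equations for 59 rates, so the system
is closed by an assumption set, stored in
`src/colontme/config/assumptions.yaml` (never in code):

- **Fixed rates** (per day): cytokine decays δ_H, δ_μ1, δ_μ2, δ_Iγ, δ_Gβ;
  naive T-cell and macrophage decays δ_TN, δ_M; and the per-capita turnover
  of each activated cell pool (T_h, T_C, T_r, D) and of cancer (its total
  per-capita death rate).  All default to 1/day.
- **Shares**: nonnegative weights summing to 1 that split each multi-term
  flux (e.g. the five HMGB1 sources, the three macrophage activation
  channels, the four cancer death channels).  Defaults are uniform.
- **α_NC** (default 0.5): the necrotic fraction of dying cancer cells;
  with the cohort identity N = C/2 this puts the necrotic decay at
  δ_N = α_NC · (cancer death rate) · C∞/N∞.

Given these, every rate is a quotient of known quantities: production
coefficients are share × flux / (source value × cofactor), influxes close
the naive-pool balances, and C0 = 2·C∞ makes the logistic factor 1/2 so the
per-capita growth is exactly twice the death rate.  The construction is
therefore exact (residuals at round-off), nonnegative by construction, and
invertible — `assumptions_from_parameters` recovers the shares and fixed
rates from any consistent parameter set, which is the identifiability
statement tested in the suite.  The defaults are explicit placeholders for
literature-derived rates; swapping them is a YAML edit.  Under the
placeholder values all five cluster equilibria are attracting (slowest mode
between −0.45 and −0.58/day), so no share search was needed; had an
unstable default appeared, a coarse deterministic grid over the share
simplex (step 0.1) was the designated fallback.

One printed reference value is near zero (the naive-dendritic density of
the resting-DC-depleted cluster, ≈0.19 cells/cm³); it is used as printed.
Exactly zero references are rejected, and callers must floor them at 1e-6
times the cohort median of that variable before non-dimensionalizing.

## Non-dimensionalization

With x̄ = x / X∞ the rescaled field is f̄(x̄) = f(X∞ x̄)/X∞; when X∞ is an
equilibrium the all-ones vector is a fixed point, Jacobians transform by
similarity (identical spectra), and trajectories of the two forms are
related exactly by the componentwise scaling.  The rescaled system is *not*
a re-parameterized copy of itself: activation rates appear with different
scale factors in the activated-cell and naive-pool equations, so the
`DimensionlessSystem` object keeps the dimensional parameters plus X∞ and
exposes the per-term scaled coefficients as a table instead.

## Sensitivity analysis

Equilibrium sensitivities come from implicit differentiation of
F(X*, θ) = 0: dX*/dθ = −(∇F)⁻¹ ∂F/∂θ, with both ∇F (the Jacobian) and
∂F/∂θ analytic (F is linear in every rate except the capacity C0, whose
column is differentiated by hand).  The Jacobian is cross-checked against
central finite differences; the implicit sensitivities against a re-solve
oracle (central differences of the equilibrium found by a Newton-type
solver at θ ± 10⁻⁴ θ).

Quantities of interest: the cancer row of the dimensionless sensitivity,
the sum of the nine cell rows (total cell density; cytokines excluded), and
the extreme eigenvalue of the Jacobian at the equilibrium as a convergence
speed proxy.  The eigenvalue quantity defaults to the literal minimum of
the real parts, with a switch (`which="max"`) for the slowest
(least-negative) mode; both conventions appear in the stability report.
Its sensitivity uses central differences with Δθ = 10⁻⁴ θ, the equilibrium
re-solved before each Jacobian evaluation, and an eigenvector-continuity
warning when branch crossing is suspected.

Rankings are computed on the dimensionless system as relative
sensitivities θ_j ∂X̄*/∂θ_j — the form invariant to rescaling the whole
reference table by a constant — in descending absolute value with ties
broken by the fixed symbol order.  The immune-only ranking masks exactly
the nine parameters of the cancer and necrotic equations.  Region-averaged
sensitivities integrate the pointwise values over the hyperrectangle
θ(1 ± h), default h = 0.10 (matching the ±10% trajectory variations; the
neighborhood size is otherwise unspecified and this is our choice), with a
nested Clenshaw–Curtis Smolyak rule (default level 2, ≈1.6×10⁴ nodes for
the 59 free rates, exact for the low-order cross terms the smooth integrand
is dominated by) and a seeded Monte-Carlo fallback; the two agree to a few
tenths of a percent on the default clusters.  Failed node re-solves are
dropped and counted.

## Dynamics

LSODA with the analytic Jacobian, rtol 1e-8 and per-variable atol of 1e-10
× the variable scale (pass the steady state as `scale` so small components
keep resolution); the time grid is geometric to resolve the fast early
transient.  `run_to_steady_state` doubles the horizon (default start 10⁴
days) until the scaled residual of the final state drops below tolerance
(default 1e-8/day).  Under the placeholder rates (unit turnover) the
clusters converge in ≈40–50 days; with literature-scale rates the horizon
would stretch into the thousands of days the default accommodates.  The
±10% envelope varies each listed parameter one at a time (two runs per
parameter, never joint corners, keeping the run count linear) and takes the
pointwise min/max across all runs plus the nominal, so the nominal
trajectory is inside the band by construction.

## Cohort mapping and clustering

Tumor size is the product of the longest and shortest dimensions (cm²).
Total density is α_dim × size / (cohort mean size) with α_dim = 1.125×10⁵
cells/cm³ — a pure scale with no effect on the dimensionless dynamics.
Each patient's immune fractions are scaled to a fixed immune budget of
0.4·α_dim (so every patient carries the same total immune density), model
variables sum their mapped cell types (the 22-type → variable table is an
editable YAML; unmapped types still count in the normalization), the naive
macrophage type plus M gives the capacity M0, and C = (2/3)(Total −
Immune), N = C/2 close the budget exactly.  The fixed budget makes the
cancer share of the total rise with tumor size, and it also makes C
negative for tumors smaller than 0.4× the mean size; mapped values keep the
exact closure (the identity is algebraic), and the smallest-tumor initial
conditions clip negatives to zero — consistent with the reference initial
rows, whose necrotic entries are zero.  A `proportional` immune-scaling
option (budget 0.4 × the patient's own total) avoids negative closures when
a cohort needs it.

Clustering runs K-means on the full 22-type fraction table (not the mapped
variables), n_init 10, fixed seed.  The elbow scan places the knee at the
last substantial relative inertia drop (≥15% and at least three times the
median of the remaining drops); a curve with no qualifying drop reports its
maximum-curvature k with the confidence flag cleared.  Steady states are
the componentwise means over the cluster's above-average-size tumors
(cytokine columns are required at this step: deconvolution provides none,
so a real-data user must supply them, and the synthetic generator emits
them); initial conditions are the smallest tumor's variables over the
steady state, ties broken by row order.

## Synthetic cohorts

The generator emulates the statistical shape of the deconvolution table:
K = 5 planted mean profiles over the 22 types (defaults echo the
qualitative cluster contrasts: two activated-macrophage-dominant patterns,
a naive-macrophage-heavy outlier with almost no resting DCs, a low-M0/
high-M2 pattern, and a balanced one), 300 patients, mean-corrected
logistic-normal within-cluster noise with σ = 0.25 (≈25% per-type
coefficient of variation, comparable to deconvolution scatter; a Dirichlet
option exists but collapses to a point mass at zero for near-zero planted
fractions, which the outlier cluster requires), log-normal size (median
0.6 cm², σ = 0.5, spanning the 0–0.25 through >1.25 cm² bins), per-cluster
cytokine means with 10% log-normal scatter, and decor-level clinical
labels.  The hidden truth carries labels, profiles and the per-cluster
steady states implied by pushing the planted means through the density
mapping at the realized sizes.  `profiles_from_steady_states` builds
profiles whose mapped immune block is proportional to the reference
clusters', for end-to-end recovery runs.

What the generator does not emulate — and what passing tests therefore do
not establish about real cohorts: correlated deconvolution estimation
error across cell types, gene-expression-level noise, informative clinical
structure, or immune totals that vary across patients.

## Numerical choices and degenerate inputs

Residuals are scaled per variable by max(|x|, 1) and read as relative
rates/day.  Equilibrium re-solves use a Newton-type solver in units of the
starting guess and accept on residual (<1e-8), not on the solver's own
flag.  Non-finite states or parameters are rejected with the offending
symbol named; negative rates, empty flux groups and shares not summing to
1 are configuration errors.  Ties (size, ranking) break deterministically
by row order and symbol order.  Eigenvalue comparisons use real parts;
complex pairs are reported as such in the stability report.

## Known limitations

- The shipped assumption config is a placeholder (uniform shares, unit
  turnover).  Equilibria, round-trips and the sensitivity *machinery* are
  exact regardless, but quantities that depend on the literature rates —
  which parameters top the immune rankings, the sign pattern of macrophage
  effects across clusters, convergence timescales, oscillation of the
  total cell density — will shift when real rates are substituted, and are
  treated as soft (warning-level) expectations in the suite.  Under the
  placeholders, cancer trajectories overshoot their steady state by
  ≈0.3–0.6% before settling, so "monotone growth" is enforced only up to a
  1% band.
- No spatial structure, stochasticity, delays or treatment terms; no
  fitting to time-course data and no uncertainty quantification of the
  derived rates.
- The cohort stage starts from deconvolution output; running deconvolution
  itself, gene-expression processing and survival statistics are out of
  scope.
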