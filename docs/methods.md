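# Methods

This note records the statistical model behind `midna`, the defaults and why
they are set where they are, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would otherwise have to
reverse-engineer.

## Data model

A study is a patient × analyte concentration matrix with a binary group
label and complete covariates.  Analysis is on the natural-log scale (the
base is configurable; only relative effects change with it).  Each cell is
observed, left-censored, or MCAR:

* a censored cell carries the information `x < log(l_j)`, where `l_j` is the
  analyte's LLOQ.  A missing cell in a column with a finite LLOQ defaults to
  censored; an explicit per-cell code (O/C/M) overrides, since
  quality-control removals must be flaggable as MCAR.  One `l_j` per analyte
  is assumed (platform-batch variation in LLOQ is not modelled).
* covariates are required complete; imputing them (logistic/polytomous
  conditionals) is out of scope since every imputation target here is a
  continuous log-concentration.

Analytes observed in fewer than a configurable fraction of patients
(default 60%) are dropped before analysis; censored and MCAR cells both
count as undetected.

## Censoring-aware chained imputation

Fully conditional specification with Bayesian normal ("norm") conditionals:
for target analyte `j`, regress its observed values on all other (currently
completed) analytes, the group indicator and the covariates; draw the
residual variance from its scaled inverse-χ² posterior (`σ² = RSS/χ²_ν`,
`ν = n_obs − k`), the coefficients from `N(β̂, σ²(XᵀX + λI)⁻¹)`, and each
missing cell from the resulting predictive normal.  Censored cells keep only
draws below `log(l_j)`; MCAR cells keep every draw.

* **Cycles.** Default `n_cycles = 10`.  Convergence of FCS is approximate by
  nature; the per-chain, per-cycle imputed-column means are recorded in
  `ImputationSet.convergence_trace` so a user can inspect stationarity.
* **Copies.** Default `M = 5`.
* **Ridge.** `λ = 1e-5` on the sweep regressions: with `p − 1` analyte
  predictors plus covariates the design can approach or exceed the observed
  row count, and a tiny penalty keeps the Cholesky factor defined without
  measurably changing well-posed fits.
* **Truncated draws.** Acceptance–rejection against the untruncated
  predictive normal, vectorised in blocks of 16 candidates per cell
  (first-acceptance semantics, identical in distribution to one-at-a-time
  rejection).  After `max_reject = 100` candidates a cell switches to exact
  inverse-CDF truncated-normal sampling computed in log-probability space
  (`Φ⁻¹(exp(log u + log Φ(z)))`), which is distributionally equivalent and
  immune to the stall that pure rejection hits when the predictive mass
  below the bound is tiny.
* **Initial state.** MCAR cells start at the observed column mean; censored
  cells at `log(l_j) − 0.01`, so the bound invariant holds from the first
  sweep.  Visit order is fixed left-to-right each cycle.
* **Determinism.** Chain `c` of a run seeded `s` uses
  `default_rng([*s, c])`; results are bit-reproducible and independent of
  how permutations are distributed over workers.

**Known bias.** The conditional regressions are fitted on the observed rows
of the target, which under left-censoring form a left-truncated sample;
slopes are attenuated and the predictive mean for censored rows is somewhat
high.  Measured against the closed-form conditional truncated-normal mean
from a known generating covariance, the imputed tail mean sits about 0.2 SD
above truth at 20% censoring.  The procedure is implemented as specified —
the alternative (a censored-likelihood/tobit conditional) is a different
method — and the bias is small compared to the complete-case alternative,
which the test suite shows loses to imputation in ≥ 90% of replicates.

## Stacking and standardisation

The `M` copies are stacked copy-by-copy into an `Mn`-row matrix.  Stacking
preserves column means but shrinks the sample variance by
`(n − 1)/(n − 1/M)`; each column is therefore centred at the stacked mean
and divided by the square root of the corrected variance
`s²_stack (n − 1/M)/(n − 1)` — an exact identity, tested to 1e-12, not an
approximation.  Standardisation is computed on both groups together and the
rows are split by group afterwards (per-group scaling would make the two
score matrices incomparable in scale; it remains available behind a flag).
Continuous covariates are standardised the same way; binary covariates stay
0/1.

## Connectivity scores

Univariate-response NIPALS with deflation, `v = 3` latent factors by
default.  NIPALS (rather than SIMPLS or a library call) keeps the per-factor
weights explicit and costs ~50 µs per fit, which matters because the
permutation test refits `2p` models per permutation; the implementation is
cross-checked against `sklearn.cross_decomposition.PLSRegression` to 1e-10
and against OLS at full rank to 1e-8.  Covariates enter the predictor block
— so they shape the latent factors and thereby adjust the fit — but their
coefficients are never scored.  `v` is clipped to the available predictor
count for very small panels.

Rescaling divides each row by its largest absolute score, so every
analyte's strongest connection has magnitude 1.  Row scaling breaks
symmetry; re-symmetrisation keeps, per pair, the entry of larger magnitude
(default, preserving each analyte's unit-strength connection) or the mean
(`resymmetrize="mean"`).  Which variant was used is part of the report
metadata, since the two yield slightly different thresholded networks.

## Modules

Edges are analyte pairs with `|ŝ| ≥ ε` — absolute value, so strong negative
association also connects.  A module is a connected component with at least
`m` members (defaults `ε = 0.4`, `m = 3`).  The alternative clique-style
reading (every within-module pair above `ε`) is deliberately not
implemented: it contradicts the path-connectivity wording of the module
definition and the topology of real networks of this kind, where modules
are chains and stars, not cliques.

## Differential tests

`𝒩` is one minus the mean Jaccard overlap of each shared analyte's modules.
Edge conventions: both networks module-free → `𝒩 = 0`; modules on one side
only (or no analyte in modules on both sides) → `𝒩 = 1`.

Because the group label is an imputation-model predictor, each permutation
of the labels re-runs the entire imputation–stacking–network pipeline; the
`d(j)` statistics for all analytes share one permutation set.  The p-value
estimator is the plain `P⁻¹ Σ I(stat(π) ≥ stat_obs)` — it can be exactly
zero — with the conservative `(b+1)/(P+1)` variant behind `add_one`.  With
`P = 99` and α = 0.05 the plain estimator is exact: rejection means the
observed statistic ranks in the top 5 of 100 exchangeable values.  No
multiple-testing correction is applied across analytes: the tests share one
fitted network and are strongly dependent, so independence-based corrections
do not apply; outputs carry raw p-values and say so.

Per-permutation sub-seeds are pure functions of `(master seed, permutation
index)`, so `n_jobs > 1` (joblib) reproduces the serial result exactly.  A
permutation whose pipeline degenerates (e.g. a zero-variance column after
relabelling) is redrawn with a shifted sub-seed, at most five times.  The
ε-sweep fits each permutation's connectivity matrices once and re-thresholds
them per ε, so grid rows share imputations and permutations — comparable,
but not independent.

## Rubin-pooled marginal reference

Per analyte: OLS ANCOVA of log-concentration on group + covariates per
imputed copy (single fit if fully observed), pooled as `β̄`, `W`, `B`,
`T = W + (1 + 1/M)B`, Wald `β̄/√T` referred to a t distribution with
Barnard–Rubin degrees of freedom (`B = 0` falls back to the complete-data
df).  This quantifies mean-level differences; the network tests quantify
connectivity differences — the two are complementary, not redundant.

## Synthetic generator

The generator emulates the features the pipeline is sensitive to: two
groups of log-normal concentrations with block covariance (within-block
correlation ρ, default 0.7; cross-block zero), per-analyte mean log-levels
drawn once around 1.5 log-μM, covariates (age, BMI, statin use, smoking)
independent of group as in a frequency-matched design, quantile-based
per-analyte censoring (default 15%) and MCAR dropout (default 2%).

The group difference is structural: a **bridge hub** analyte that sits in
its own singleton block and, in the case group only, correlates at
`hub_coupling` with every member of two target blocks — two modules
isolated in the control network, bound into one larger module through the
hub in the case network.  The member-hub variant (a block member coupling
to a second block) is also expressible via `hub_analytes`/`hub_targets`
pairs.  `hub_coupling` defaults to `0.65ρ`: couplings approaching ρ itself
make the joint correlation matrix indefinite once blocks have several
members (the PD limit is ≈ 0.5 at ρ = 0.7 with five-member blocks), and
0.65ρ keeps a clear margin while remaining a strong coupling.  Infeasible
configurations raise rather than being silently repaired.

What the generator does **not** emulate: mass-spectrometry technical noise,
batch effects, platform-specific LLOQ variation within an analyte,
covariates correlated with group, non-normal log-concentration
distributions, and MNAR mechanisms other than deterministic left-censoring.
Passing tests therefore demonstrate correctness of the machinery and
behaviour under the stated generative model, not robustness to those
real-data complications.

## Problem sizes used in the test suite

The suite runs the full pipeline at deliberately modest sizes chosen to make
its statistical claims sharp per unit of compute: the type-I-error study
uses 200 replicates of n = 60, p = 8, M = 2, P = 99 with 3 MICE cycles
(size of the d-test checked against the exact binomial 99% band); hub
recovery uses 50 replicates of n = 300, p = 20 at full pipeline defaults;
the bias comparison uses 100 replicates of n = 100, p = 4.  Null validity
of the permutation test is a rank-exchangeability property and does not
depend on the number of MICE cycles.

## Known limitations

* The truncation-selection bias of the conditional fits (above) grows with
  the censoring fraction; columns censored beyond ~40% should be interpreted
  with care (the 60% detection filter keeps the default pipeline well away
  from this regime).
* `𝒩` is coarse: identical module memberships give 0 even if edge weights
  differ arbitrarily (that difference is `d(j)`'s job).
* Permutation p-values have resolution `1/P`; `P = 500` gives 0.002.
* The PLS score matrix is dense; sparse alternatives (penalised regressions)
  are out of scope.
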