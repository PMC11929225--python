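# Methods

## The data-generating mechanism

Five individual-level variables `(Z, L, N, X, Y)` follow a recursive linear
structural system in which every variable has unit variance. Directed
edges carry standardised path coefficients (`rho1`–`rho7`, see README);
each child equals the coefficient-weighted sum of its parents plus an
independent residual scaled so the child's variance is one. Two modelling
assumptions frame everything downstream: *population homogeneity* (the same
coefficients hold in every cluster) and *no interference* (one person's
variables do not affect another's) — appropriate for, e.g., non-communicable
disease outcomes in administrative health data, and deliberately excluding
infectious-type peer effects or between-cluster heterogeneity.

Because the system is linear and standardised, it implies an exact
correlation matrix, computed by walking the variables in topological order
(`path_model.implied_correlation`; equivalent to Wright's path tracing).
Feasibility requires each implied residual variance to be strictly
positive; configurations violating this (possible when a variable's parents
jointly "explain" more than unit variance) are rejected with a validation
report. Residual variances are derived on the fly, never stored; the
topological order uses lexicographic tie-breaking in the canonical
`(Z, L, N, X, Y)` order so results are deterministic.

## Sampling populations

*All-normal marginals.* Populations are drawn directly from
`N(0, Sigma)` via a Cholesky factor (`sample_mvn`).

*Mixed normal/Bernoulli marginals.* Binary outcomes or confounders change
the problem: no closed-form joint distribution has the target correlations
and exact margins. `sample_mixed` uses iterative rank matching: each
variable gets a fixed pool of `n` values from its marginal; each iteration
draws a multivariate-normal "shape" sample under an intermediate
correlation matrix and replaces every column by its rank-matched pool, so
output marginals are exact permutations of the pools by construction. The
intermediate matrix is updated by the residual (target minus realised
correlation) and repaired to a valid correlation matrix by eigenvalue
clipping at 1e-8 plus rescaling to unit diagonal. The best sample by
root-mean-square residual is kept; iteration stops after 10 rounds without
an improvement of at least 1e-4, or 50 rounds (all exposed as controls).

Choices that matter:

- Bernoulli pools contain exactly `round(n*p)` ones rather than i.i.d.
  draws, so realised prevalence is controlled — this stabilises the
  rare-outcome setting, where binomial noise in the prevalence would
  otherwise dominate.
- Rank ties (only possible in binary pools) are broken by the shape
  column's order statistics via a stable sort, the standard rank-matching
  convention.
- Each variable's pool comes from an independently spawned substream of the
  replicate seed, so changing one marginal leaves the others' draws intact.
- Correlations between a Bernoulli(p) margin and a normal margin cannot
  exceed `phi(Phi^-1(1-p)) / sqrt(p(1-p))` (the point-biserial bound,
  ~0.585 at p = 0.1); targets beyond the attainable bound are recorded as
  feasibility warnings in the diagnostics rather than errors, since the
  generator still returns its best approximation.

## Clustering: making cluster size causal

The latent `N_i` is converted into `C` integer cluster sizes by: (a)
stable-sorting individuals by `N_i`; (b) affine-rescaling the sorted values
to mean `n/C` and a target sample sd (default 10, sd with denominator
`n-1`); (c) splitting into `C` evenly sized consecutive subsets (the first
`n mod C` subsets take one extra member); (d) drawing one candidate per
subset uniformly at random and rounding half-away-from-zero (default), or
rounding the subset mean; (e) adding/subtracting 1 at uniformly chosen
clusters until the sizes sum to `n` exactly, never pushing a size below 1;
(f) assigning the sorted individuals to clusters in contiguous blocks.

Step (f) is what gives cluster size its causal content: clusters are bands
of the `N_i` distribution, so any variable correlated with `N_i` (here `L`,
through `rho6`) varies systematically across clusters of different sizes.
The rounding in (d) and the adjustment noise in (e) are not nuisances —
they are precisely why cluster size is an *imperfect* surrogate for the
latent confounder, which is the phenomenon under study. The floor at 1 in
step (e) is this implementation's choice for degenerate spreads; a warning
is logged when candidates round below 1.

Aggregation is deterministic: means for continuous variables, counts of
ones for binary ones; `N_j` is the assignment's integer size (not the mean
of `N_i`). The aggregated latent confounder `L_j` is stored for diagnostics
and truth oracles but flagged latent — model-fitting code refuses to touch
it, mirroring its unobservability in real data.

## The analysis models

Model 1 (multilevel): `Y_i ~ X_i + N_j (+ Z_i)` with cluster random
intercepts — the minimal multilevel structure consistent with mixed-effects
modelling; no random slopes. Continuous outcomes use REML via statsmodels
`MixedLM`; the coefficient vector is then re-profiled at the fitted
variance components through the exact within/between GLS decomposition,
which is numerically identical away from boundaries but remains exact when
the residual variance hits zero (where the estimator degenerates
continuously to the between-cluster regression — the aggregation
consistency oracle in the tests exploits this). Binary outcomes use a
Poisson log-link model so effects are comparable across models on one
scale; the point estimate comes from a pooled Poisson fit with
cluster-robust variance and the cluster-size covariate, a marginal stand-in
for the random-intercept Poisson fit that is flagged in the estimate
metadata (`random_intercept: False`). Point estimates, which drive all
bias summaries, are the quantity of interest.

Models 2–7 (ecological, per the README table) are fitted on the `C`-row
cluster table: OLS for continuous outcomes; for binary outcomes models 2,
3 and 7 are Poisson (log link) on counts and models 4–6 are linear on
proportions. No restandardisation of aggregated variables (variance
shrinkage under aggregation is part of the phenomenon), no weighting by
cluster size, intercepts always included, and zero counts are left to the
Poisson likelihood. Ratio-model (4–6) estimates live on a different scale
and are divided by the number of clusters `C` before comparison with truth;
the divisor is configurable because alternatives (mean cluster size) are
defensible and the convention is not uniquely determined.

Adjustment for regular confounding (`Z_i` at level 1, `Z_j` at cluster
level) is included exactly when the scenario activates `rho2`/`rho3`.
Non-converged fits are excluded from medians and their count reported.

## Scenarios and truth

- Scenario 1: regular confounding only (`rho2 = rho3 = 0.3`).
- Scenario 2: latent confounding only (`rho4 = rho5 = 0.3`, `rho6 = 0.8`).
- Scenario 3: both, causally unrelated (scenario 1 + 2, `rho1 = 0`).
- Scenario 4: both, causally related — `rho1 = 0.8`. (The strength of the
  `Z -> L` path follows the summary table's caption; the closed-form
  within-cluster bias confirms only 0.8 is consistent with the reported
  scenario-4 multilevel bias, 0.0285 predicted vs 0.028 reported, whereas
  0.5 would be indistinguishable from scenario 3.)
- 4a: scenario 4 with a rare binary outcome (default prevalence 0.1 %,
  exposed as a parameter since plausible values between 0.01 % and 0.4 %
  exist); 4b: binary latent confounder (10 %), continuous outcome; 4c:
  both binary at 10 %.

Defaults mirror the study conditions: `n = 100000` (a subregion-sized
population), `C = 100` (small-area clusters, mean size 1000, size sd 10),
effect grid `rho7 = 0.0 .. 0.5` in steps of 0.1, 1000 replicates,
confounding coefficients 0.3, surrogate strength `rho6 = 0.8`.

*Truth.* For continuous outcomes the estimand is `rho7` itself. For binary
outcomes the log link changes the effect scale, so truth comes from an
internal oracle: simulate one population of at least 10^6, fit the
individual-level Poisson model of `Y` on `X` fully adjusted for both
confounders (`Z` and `L` — possible only because the simulator knows `L`),
and take the `X` coefficient; results are cached per scenario
configuration and the null (`rho7 = 0`) returns 0 exactly without
simulation. A published reference column for the 10 %-prevalence
transformation (0.30/0.60/0.90/1.20/1.33 at `rho7` = 0.1–0.5) is shipped
as `BINARY_TRUTH_REFERENCE` and compared against the oracle in
`truth_reference_diagnostic`; discrepancies are reported, never silently
resolved, because the reference's exact derivation is not available.

## Seeding and reproducibility

Every replicate derives its streams from the key
`(base_seed, scenario_code, round(rho7*1000), replicate_index)` via numpy
`SeedSequence` spawning. Any single cell of the design can be re-run in
isolation, and parallel execution by replicate is byte-identical to serial
order. The truth oracle and the cluster builder get separate substreams.

## What the tests do and do not show

The acceptance suite re-derives the headline bias surface at full
population scale (`n = 100000`, `C = 100`) but with reduced replicate
counts — 100 for continuous outcomes, 50 for binary — sized against the
very small replicate spreads of the multilevel estimates (sd ≈ 0.003), so
medians are resolved well inside the comparison tolerances. Unit and
property tests run at much smaller `n`.

The generator emulates the *study conditions*, not real data: marginals are
exactly standard normal or Bernoulli, relationships are linear on the
latent scale, coefficients are homogeneous across clusters, and there is no
interference, measurement error, or missingness. Passing tests therefore
demonstrate the internal consistency of the machinery and the size of
aggregation and residual-confounding biases *under this mechanism*; they do
not bound ecological-analysis bias for data generated differently (e.g.
with between-cluster heterogeneity, where both analyses can fail in new
ways).

One designed check is expected to fail and is retained deliberately: the
ablation test asserting that severing `L -> N` (`rho6 = 0`) removes the
scenario-2 multilevel bias. The causal structure predicts the opposite —
with the link severed, cluster size carries no confounder signal, the
latent confounder is entirely unadjusted, and the bias rises to the
closed-form marginal value `rho4*rho5 = 0.09` (measured ≈ 0.090). The
correct null statement — that the cross-level correlation `Corr(N_j, L_j)`
vanishes when `rho6 = 0` — is verified in the cluster-builder diagnostics
tests.

## Known limitations

- The binary multilevel point estimate is marginal (pooled Poisson with
  cluster-robust variance), not conditional on cluster; with the modest
  cluster-level variation induced here the difference is well below the
  comparison tolerances, but it is flagged per-estimate in metadata.
- The rank-matching generator offers no feasibility guarantee for extreme
  targets (e.g. correlations beyond the point-biserial bound at low
  prevalence); it reports warnings and its residual diagnostics instead.
- Only the five-variable diagram template is supported; arbitrary DAGs,
  nonlinear structural equations, varying `C` within a run, and
  interference are out of scope.
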