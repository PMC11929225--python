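# hiersim

Causally structured hierarchical data simulation, and a head-to-head
evaluation of multilevel versus ecological regression for recovering
individual-level causal effects.

## The problem

Population health data are hierarchical: people nested in practices,
neighbourhoods, or administrative areas. When individual-level data are
unavailable, analysts fall back on *ecological* regression — one row per
cluster, aggregated variables — and often adjust for cluster size on the
informal grounds that it proxies unobserved confounding. Whether that
rescues causal estimates, and by how much it fails, can only be quantified
by simulating data whose cross-level structure has known causal origins.

`hiersim` simulates exactly that. Five individual-level variables follow a
linear structural system with standardised path coefficients:

```
rho1: Z -> L     rho2: Z -> X     rho3: Z -> Y
rho4: L -> X     rho5: L -> Y     rho6: L -> N
rho7: X -> Y     (the causal effect of interest)
```

`Z` is an observed ("regular") confounder, `L` a latent confounder, `X` the
exposure, `Y` the outcome, and `N` a latent size-driver. Because every
variable is standardised, the diagram implies an exact Pearson correlation
matrix (Wright's path tracing), from which populations are drawn — as
multivariate normal, or by an iterative rank-matching generator when some
marginals are Bernoulli. A dedicated algorithm converts the latent `N_i`
into `C` integer cluster sizes and a cluster assignment, so cluster size
`N_j` inherits `L`'s signal: a cross-level association with prespecified
causal origins. Aggregation (means for continuous variables, counts for
binary ones) produces the cluster table for ecological analysis.

Seven models are then fitted and compared against the simulated truth:
model 1 is the multilevel analysis (`Y_i ~ X_i + N_j` with cluster random
intercepts; Poisson log link for binary outcomes), models 2–7 are
ecological designs differing in how they adjust for cluster size (linear
term, reciprocal, ratio transforms, log-size offset). Bias is summarised
per scenario, effect size and model as the median and standard deviation of
`estimate − truth` over replicates.

## Worked example

Scenario 2 (latent confounding only: `rho4 = rho5 = 0.3`, `rho6 = 0.8`) at
population size 100 000 with 100 clusters, 20 replicates:

```python
import numpy as np
from hiersim import ScenarioSpec, run_scenario, implied_correlation

spec = ScenarioSpec.preset("2", n=100_000, C=100, replicates=20,
                           effect_grid=(0.0, 0.3), base_seed=42)
print(np.round(implied_correlation(spec.diagram(0.3)), 3))
result = run_scenario(spec, models=(1, 2))
print(result.summary()[["rho7", "model_id", "median_bias", "sd_bias"]]
      .to_string(index=False))
```

```
[[1.    0.    0.    0.    0.   ]
 [0.    1.    0.8   0.3   0.39 ]
 [0.    0.8   1.    0.24  0.312]
 [0.    0.3   0.24  1.    0.39 ]
 [0.    0.39  0.312 0.39  1.   ]]
 rho7  model_id  median_bias  sd_bias
  0.0         1     0.033537 0.004064
  0.0         2     0.227490 0.125048
  0.3         1     0.032397 0.002331
  0.3         2     0.111318 0.087955
```

The matrix is the diagram-implied correlation over `(Z, L, N, X, Y)` —
e.g. `Corr(N, X) = rho6 * rho4 = 0.24`. The summary shows the two headline
phenomena: the multilevel analysis carries a small residual-confounding
bias (~0.03, tight across replicates) because cluster size is an imperfect
surrogate for `L`, while the ecological analysis suffers a larger
aggregation bias with roughly thirty-fold greater replicate spread — any
single ecological study is very unreliable even when its median is
tolerable.

A CLI mirrors the library:

```bash
hiersim run --scenario 2 --outcome continuous --reps 100 --seed 1 --out runs/s2
hiersim summarize --in runs/s2 --out table.csv
hiersim truth --scenario 2 --outcome binary --rho7 0.3
```

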