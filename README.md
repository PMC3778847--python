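# deprivmap

Small-area deprivation indices and Bayesian ecological regression of
mortality, for epidemiologists and health-geography researchers working
with census-tract data.

The package implements a two-stage analysis:

1. **Deprivation index (DP2).**  Tract-level socioeconomic indicators
   x_ij (unemployment, education, housing and neighbourhood conditions,
   …) are oriented so higher = more deprived, z-scored, and aggregated
   with the Pena distance

   DP2_i = Σ_j (z_ij − x*_j)/σ_j · (1 − R²_{j·1..j−1}),

   where indicators are ordered by squared correlation with the index
   (iterated to a fixpoint) and each indicator is discounted by the
   share of its variance already explained by its predecessors — so
   duplicated information counts once while every variable stays in the
   index.  The index is cut into equal-count quintiles (Q1 = least
   deprived).

2. **Ecological regression (modified BYM).**  Death counts follow

   O_i ~ Poisson(Pop_i · exp(α + Σ_k β_k 1[Q_i = k+1]
          + β₅·age4564_i + β₆·age65_i + υ_i + S_i)),

   a Besag–York–Mollié model with the *population* as offset (a crude-
   rate model, with tract age structure as covariates rather than an
   age-standardized response — avoiding mutual-standardization bias),
   iid heterogeneity υ and an intrinsic CAR spatial effect S on the
   tract adjacency graph.  exp(β_k) is the relative risk of quintile
   k+1 versus Q1.  Two inference engines are provided — a
   Metropolis-within-Gibbs MCMC sampler and an INLA-style Laplace
   approximation with central-composite-design integration of the two
   hyperparameters — plus DIC and conditional-predictive-ordinate (CPO)
   model comparison with an exact leave-one-out oracle.

Because registry and census microdata cannot be redistributed, the
package ships a synthetic small-area generator (`deprivmap.synthetic`)
producing lattice studies with spatially correlated indicators, a known
latent deprivation gradient and Poisson counts with known effects, so
the whole chain is testable end to end.  See `docs/methods.md` for the
model details and design choices.

## Worked example

```python
import numpy as np
from deprivmap import (SimulationConfig, make_study, DP2Index,
                       assign_quintiles, BYMPoissonRegression,
                       posterior_rr)
from deprivmap.evaluate import attach_diagnostics

study = make_study(SimulationConfig(rows=20, cols=20, seed=7))

dp2 = DP2Index(specs=study.specs)
index = dp2.fit_transform(study.indicators)
quintiles = assign_quintiles(index)
print(np.corrcoef(index, study.truth["latent"])[0, 1])   # 0.993

outcomes = study.outcomes.assign(quintile=quintiles.labels)
model = BYMPoissonRegression(engine="laplace", seed=7)
model.fit(outcomes, graph=study.graph)
diag = attach_diagnostics(model.result_)
print(posterior_rr(model.result_))
```

Output:

```
         parameter  estimate   lo95  hi95
             RR Q2     1.236  1.018 1.501
             RR Q3     1.358  1.116 1.651
             RR Q4     1.346  1.098 1.650
             RR Q5     1.542  1.252 1.899
      beta_age4564     0.051 -0.009 0.111
        beta_age65     0.058 -0.001 0.116
sigma_S (mean, SD)     0.403  0.328 0.478
sigma_v (mean, SD)     0.471  0.432 0.510
DIC 2665.3  p_eff 334.5  -mean log CPO 3.856
```

The reconstructed index tracks the latent deprivation gradient at
r = 0.99.  The fitted relative risks rise across quintiles — tracts in
the most deprived fifth carry ~1.5× the mortality of the least
deprived, with a 95% interval excluding 1 (the generating truth here is
exp(0.3) = 1.35) — and the random-effect SDs are near their generating
values (0.3 spatial, 0.5 heterogeneity).  Lower DIC / −mean log CPO
means a better model when comparing specifications.

The same stages are exposed as a CLI (`deprivmap simulate | index |
adjacency | fit | run | experiment`); `deprivmap run --config run.yaml`
executes simulate → index → fit → evaluate and writes posterior tables,
a report in the conventional RR-per-quintile layout, and a hashed run
manifest.

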