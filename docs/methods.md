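# Methods

`deprivmap` implements a two-stage small-area analysis: a census-tract
deprivation index built by aggregating socioeconomic indicators with the
Pena DP2 distance, and an ecological Poisson regression of tract death
counts on the quintiled index with spatially structured and unstructured
random effects.  Everything is exercised against a synthetic lattice
generator with known ground truth, because registry microdata of the
kind such studies use cannot be redistributed.

## The DP2 deprivation index

Given tract-by-indicator data, favorable indicators (e.g. university
education) are negated so that larger always means more deprived, and
every column is z-scored.  With reference base `x*` (default: the
column-wise minimum of the standardized matrix, i.e. the least-deprived
observed profile) the index is

    DP2_i = sum_j (z_ij - x*_j) / sigma_j * (1 - R^2_{j | 1..j-1}),

where `R^2_{j|1..j-1}` is the coefficient of determination of indicator
j regressed (OLS with intercept) on the indicators preceding it in the
current ordering, and the ordering ranks indicators by decreasing
squared correlation with the current index.  Iteration starts from the
Frechet index (all weights 1) and stops at an ordering fixpoint, with a
secondary guard on the maximum index change (`tol`, default 1e-10;
`max_iter` default 100).  The first-ordered indicator always carries
weight 1; an exact duplicate of an existing column receives weight 0, so
only redundant information is discounted, never a variable as a whole.

Numerical choices: correlation ties are broken by original column
order, which makes the converged ordering deterministic and invariant
to input column permutations on generic data; rank-deficient predecessor
blocks are handled by minimum-norm least squares, which leaves fitted
values and hence R^2 well defined; missing values are rejected rather
than imputed (census aggregates are complete).  Because z-scoring
absorbs any affine rescaling of a raw column, the index is invariant to
units of measurement.

Quintiles are equal-count by rank (ties broken by tract order), label 1
= least deprived; a constant index cannot be quintiled and is an error.

## The ecological regression

For tract i with population `Pop_i` and death count `O_i`:

    O_i ~ Poisson(Pop_i * exp(eta_i))
    eta_i = alpha + sum_{k=1}^{4} beta_k 1[Q_i = k+1]
            + beta5 * age4564_i + beta6 * age65_i + upsilon_i + S_i

- The offset is the *population*, so the model describes the crude
  rate; tract age structure (shares aged 45-64 and 65+) enters as
  covariates.  This avoids the "mutual standardization" bias of
  regressing an age-standardized response on unstandardized predictors.
- The deprivation index enters as quintile indicators with the least
  deprived quintile as reference, capturing non-linearity and blunting
  concurvity between a spatially smooth deprivation field and `S`.
- `upsilon_i ~ N(0, sigma_v^2)` iid heterogeneity; `S` follows an
  intrinsic CAR prior on the tract adjacency graph, `p(S) ∝
  tau_S^{rank(Q)/2} exp(-tau_S/2 S'QS)` with `Q = D - W`, constrained to
  sum to zero within each graph component.  Isolated tracts keep `S = 0`
  and contribute through `upsilon` only.
- Priors: `alpha, beta ~ N(0, 1000)`; `tau_v, tau_S ~ Gamma(1, 5e-4)`
  (vague disease-mapping defaults), all configurable via `Priors`.

**Scale convention for sigma_S.**  The ICAR precision is unscaled
(classic BYM), but `1/sqrt(tau_S)` is not the typical marginal spread of
`S` — on a 30x30 lattice the geometric-mean marginal variance of the
unit-precision ICAR is ~0.83.  Both the generator and the fitted model
therefore define `sigma_S` on the *marginal* scale: the generator
rescales its ICAR draw to unit geometric-mean marginal SD before
multiplying by `sigma_S`, and fits report `sigma_S =
sqrt(gv / tau_S)` with `gv` the geometric-mean marginal variance of the
graph's ICAR structure.  This makes parameter recovery well-posed; the
prior itself remains on the unscaled precision.

## MCMC engine

Metropolis-within-Gibbs with six move families per iteration:

1. single-site random-walk updates of the fixed effects;
2. simultaneous elementwise random-walk updates of `upsilon` (valid
   because its full conditionals are mutually independent);
3. elementwise updates of `S` swept over a greedy colouring of the
   graph (no two sites in a colour class are neighbours);
4. likelihood-invariant *translation* moves, `(gamma_j + d, upsilon -
   d x_j)` and, on connected graphs, `(gamma_j + d, S - d (x_j - mean
   x_j), alpha - d mean x_j)`, accepted on the priors alone;
5. likelihood-invariant *swap* moves `(upsilon_i + d, S_i - d)` per
   colour class;
6. global field *rescales* `u' = c u` and `S' = c S` with Gaussian
   `log c` (Jacobians `n log c` and `rank(Q) log c`), which travel the
   ridge between a field's amplitude and its precision.

The swap, translation and rescale families are essential: the posterior
has long ridges between each coefficient and the mean of the fields
over its covariate support, between the two fields themselves (the
weakly identified BYM decomposition), and between each field's scale
and its precision.  Plain site-wise updates mix across these ridges
extremely slowly — fixed-effect effective sample sizes of tens per
30,000 draws, with independent seeds disagreeing; the invariant and
rescale moves raise ESS to around a thousand and bring independent
chains into agreement.

After every sweep `S` is recentred; on a connected graph the mean is
absorbed into the intercept so the likelihood is untouched (for
disconnected graphs each component is recentred without compensation —
the standard convention).  Precisions are drawn from their exact
conjugate Gamma conditionals, `tau_S` with shape `a + rank(Q)/2` and
rate `b + S'QS/2`.  Proposal scales adapt toward 0.44 acceptance during
burn-in only.  The fields initialize on the split crude-rate residuals
— starting at zero is a trap, since the first conjugate draw would set
`tau ~ shape/rate` and pin the fields.

Streaming accumulators collect posterior moments, the per-draw deviance,
the mean linear predictor, harmonic-mean CPO terms and predictive mass
for masked tracts, so latent-field draws are never stored; the small
fixed-effect and hyperparameter chains are kept near-unthinned (up to
20,000 stored draws).  Split-R-hat (4 segments) and an autocorrelation
ESS (initial-positive-sequence estimator, lag window 5,000) are
attached per fixed effect; the long window matters because the
variance-split ridges induce long-memory autocorrelation that a short
window — or a heavily thinned series — would hide, understating the
Monte Carlo standard errors.

## Laplace/CCD engine

An INLA-style approximation with hyperparameters `theta = (log tau_v,
log tau_S)`:

1. For a given `theta`, the Gaussian approximation of `p(x | theta, y)`
   is found by Newton iteration on the Poisson log-likelihood plus the
   GMRF prior; the sum-to-zero constraint is imposed at each step by
   conditioning by kriging.  Factorizations use sparse LU with the
   `MMD_AT_PLUS_A` ordering.
2. `p(theta | y)` is approximated by the Laplace identity — joint
   density over the constrained Gaussian approximation at its mode —
   including the constraint correction `-1/2 log det(A H^-1 A')`.
3. The mode of the hyperposterior is located by a coarse 3x3 scan of
   log-precision space followed by bounded L-BFGS-B polish; its
   curvature is estimated by central finite differences (h = 0.3,
   eigenvalues floored at 0.05); support points are the mode plus eight
   star/corner points of a central composite design at radius 1.7 in
   the standardized metric.  Mixture weights are the normalized
   hyperposterior values with equal volume factors (the exact CCD
   quadrature weights are not replicated; the mixture re-weighting
   captures the dominant variation).
4. Latent marginals are Gaussian mixtures over the support points.  The
   Gaussian centre (the conditional mode) is shifted by the classical
   third-derivative Laplace mean correction `1/2 C B'(f''' ∘ Var(eta))`
   (`f''' = -curvature` for Poisson), which removes the mode-vs-mean
   skewness bias; without it fixed-effect means are biased by ~0.01 at
   n = 400, beyond the Monte Carlo error of a well-mixed reference
   chain.  Fixed-effect quantiles solve the mixture CDF exactly.

`latent_summaries=False` skips the dense covariance pass (and the mean
correction), returning mode-centred fixed-effect summaries — an order
of magnitude faster, used for experiment sweeps where only coefficient
point estimates and intervals matter.

The observation model is pluggable (`PoissonObs`/`GaussianObs`); with a
known-variance Gaussian response the whole construction is exact and is
validated against the constrained GLS closed form in the tests.

## Model comparison

- `DIC = Dbar + p_eff`, `p_eff = Dbar - D(posterior mean of the latent
  field)` (classic Spiegelhalter form; the identity is asserted
  exactly).  For the Laplace engine `Dbar` uses `E[e^eta] =
  exp(m + v/2)` per mixture component.
- `CPO_i`, the leave-one-out predictive density, is computed from MCMC
  draws by the harmonic-mean identity `CPO_i = 1 / E[1/p(O_i |
  eta_i)]`, with the likelihood floored at 1e-300 and a per-tract
  instability flag when a single draw carries >10% of the harmonic sum.
  The summary is `-mean_i log CPO_i`; lower is better for both criteria.
- For the Laplace engine a direct `1/p` quadrature diverges (the
  integrand grows double-exponentially against Gaussian tails), so CPO
  uses the leave-one-out *cavity*: tract i's quadratic likelihood
  contribution is removed from its linear-predictor marginal and the
  (bounded) Poisson pmf is integrated against the cavity Gaussian by
  Gauss-Hermite quadrature, mixture-weighted over support points.
- `exact_loo_cpo` is the arbiter: it refits with tract i's likelihood
  term masked (the tract stays in the random-effect structure) and
  returns the posterior predictive probability of the held-out count;
  it refuses studies beyond 200 tracts.  Harmonic-mean CPO agrees with
  exact refits within 10% on a 20-tract toy study with moderate random
  effects (sigma = 0.2); under strong heterogeneity the harmonic
  estimator converges too slowly to validate tract-by-tract, which is
  precisely why the flags and the oracle exist.
- For model *comparison* under strong heterogeneity, prefer the
  Laplace engine's deterministic diagnostics: the true-vs-null CPO
  advantage of a correctly specified deprivation term is small (a few
  log units over hundreds of tracts, because the random effects can
  absorb much of a smooth covariate's pattern) and harmonic-mean noise
  at sigma_v = 0.5 is an order of magnitude larger, enough to invert
  the ranking.

## Synthetic-data generator

A rook-adjacency lattice carries a latent deprivation field built as a
variance-weighted mixture of a unit-marginal-SD ICAR draw and iid
noise; `spatial_range` in [0, 1] is the spatial weight (0 = white
field, 1 = fully ICAR-smooth).  Indicators load linearly on the latent
field with iid Gaussian noise and are mapped to a percentage-like scale
(mean 30, SD 12), all adverse.  Quintiles for the generative model come
from the rank of the latent field itself.  Age-structure shares are
drawn around an urban pyramid (45-64 share ~ 0.25, 65+ share ~ 0.18);
in the confounded scenario the 65+ share is constructed to correlate
with the quintile rank at a target Pearson r.  Populations are uniform
integers in [500, 2000], matching the ~1200-inhabitant tracts of
Spanish urban censuses.  Counts follow the ecological model above with
`alpha = log(baseline_rate)`.  One seed drives named sub-streams
(field, noise, age, counts), so identical configurations reproduce
bit-identical studies.

Defaults are the reference study conditions used throughout the tests:
30x30 lattice, 16 indicators with loading 1 and noise SD 0.3, spatial
weight 0.7, baseline rate 0.01, quintile log-RRs (0.1, 0.2, 0.2, 0.3),
age effects (0.5, 1.5), `sigma_S = 0.3`, `sigma_v = 0.5`.

What the generator does *not* emulate: the marginal distributions of
real census indicators (only their correlation with a common gradient),
municipal boundary effects in adjacency, temporal drift between census
and mortality windows, and age-by-cause interactions.  Passing tests
therefore demonstrate internal consistency of index, model and
inference under the stated generative family — not performance on real
registry data.

## The two methodological experiments

Both experiments replicate a generative process with known effects and
compare two model specifications.

**Mutual standardization.**  In a scenario where the 65+ share
correlates with the deprivation quintile (r = 0.6) and age strongly
affects mortality (beta_age65 = 2), arm A standardizes only the
response: expected counts from an age-only Poisson GLM become the
offset and age is dropped from the model.  Arm B is the package's
specification (population offset + age covariates).  Reported per arm:
mean bias, mean |bias|, RMSE and CI coverage of the top-quintile
log-RR.

**Concurvity.**  The latent deprivation field is generated fully
ICAR-smooth (`spatial_range = 1`), the same spatial family as `S`.  Arm
'quintile' enters it as standardized equal-count quintiles, arm
'continuous' as the raw unstandardized field.  Error is measured on the
four implied quintile contrasts (for the continuous arm, the fitted
slope times the difference in group means), with the correlation
between the fitted `S` and the covariate as a diagnostic.

Experiment defaults use a *mechanism-isolation* design: baseline rate
0.02 and random-effect SDs (sigma_S, sigma_v) = (0.2, 0.15), smaller
than the reference recovery conditions.  With the reference values the
per-replicate estimation noise in the top-quintile coefficient (~0.12
at 400 tracts) swamps the systematic standardization bias (~0.1 — the
projection of the quintile pattern onto the age covariate is bounded by
r^2), and no finite replicate budget separates the arms cleanly.  The
gentler conditions keep Poisson and random-effect noise below the
systematic effects the experiments are about, without changing either
mechanism.

## Problem sizes and budgets

Test-suite sizes are chosen to keep the full suite single-CPU friendly
while leaving each check statistically meaningful: parameter recovery
uses 20 replicate 30x30 studies
with 7,000 kept MCMC draws each (ESS ~200-300 per fixed effect); engine
agreement uses five 20x20 studies against 20,000-draw chains; the CPO
oracle uses the 20-tract toy with 40,000-draw full fits and 12,000-draw
leave-one-out refits; the experiments run 20 replicates each at
moderate lattice sizes.  The sampler's module defaults (20,000 kept /
5,000 burn-in) are sized for single production fits, not for replicate
sweeps.  `scripts/acceptance.py` re-runs the whole chain — index
construction, both engines, model comparison and both experiments — at
the same sizes from a single command-line seed.

## Known limitations

- With few tracts (~100) and the vague Gamma priors, the (sigma_v,
  sigma_S) posterior is a ridge with mass near both collapse corners;
  the two engines can legitimately disagree there and hyperparameter
  summaries are prior-sensitive.  At the study sizes of interest
  (hundreds to thousands of tracts) the posterior is well behaved.
- The CCD integration uses equal volume weights; strongly skewed
  hyperposteriors are represented only to second order.
- Harmonic-mean CPO is noisy for outlying tracts under strong
  heterogeneity; consult the per-tract instability flags and the exact
  refit oracle.
- No BYM2/scaled-precision variant, no spatio-temporal terms, no
  zero-inflation, and no shared-component multivariate models.
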