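# Methods

## The model

`mmbm` implements multilevel multinomial behavioural models (MMBMs) for
cross-cultural time-allocation data: repeated coded observations of children
and adolescents, each falling into one of five activity categories —
childcare, food production, domestic work, play, and a residual "other"
category that serves as the reference.

Observations follow a categorical (generalized Bernoulli) distribution. For
child *i* in society *j*, the log-odds of activity *k* against the reference
are

    log(π_kij / π_5ij) = β_k + ν_individual_ki + ν_society_kj + Σ_m β_km x_im ,
    k ∈ {1,…,4},

with the five category probabilities recovered through the softmax link
(reference logit pinned at 0). The individual-level effects
(ν_individual_1i,…,ν_individual_4i) and society-level effects
(ν_society_1j,…,ν_society_4j) are each multivariate normal with mean zero and
a full 4×4 covariance Ω = diag(σ)·R·diag(σ), so the model learns, for
example, whether children who do more childcare than expected also do more
domestic work (a positive ρ between those categories).

Because observations of one child share a linear predictor, the categorical
likelihood collapses to a multinomial in the per-child category counts;
the pointwise (per-observation) log-likelihoods needed for WAIC are kept
separately.

Five candidate fixed-effect structures are predefined:

| model | fixed effects beyond the intercepts |
|---|---|
| 1 | none (intercept only) |
| 2 | age class + gender + age×gender + proportion non-foraged food (z) |
| 3 | model 2 + NPP (z) + annual precipitation (z) + annual mean temperature (z) |
| 4 | model 2 + dangerous mammal density (low/high) + water quality/quantity (1–4) |
| 5 | model 2 + gendered division of food production labour + division×gender |

Girls, early childhood, low mammal density are the reference levels. The
water rating enters as a single numeric covariate; the division statistic
enters on its natural −2…2 scale.

## Priors

The priors are weakly informative for logit-scale hierarchical models and
configurable via `PriorConfig`:

* fixed effects: Normal(0, 2.5) — permissive on the log-odds scale without
  endorsing near-deterministic probabilities;
* random-effect scales σ: Exponential(1) — mass near zero with a heavy
  enough tail for large behavioural heterogeneity;
* correlation matrices: LKJ(2) — mild shrinkage towards independence.

The LKJ density is evaluated in the canonical-partial-correlation (CPC)
parameterization of the correlation Cholesky factor. Under LKJ(η) the CPCs
are independent shifted-Beta variables on (−1, 1) whose shape depends only
on the column index — a fact derived from the transform Jacobian and
verified in the tests against the K=2 closed form and a K=3 numerical
integration.

## Covariates

Society-level predictors are constructed exactly as an ethnographic
cross-cultural analysis would:

* **Diet composition.** Per-source caloric estimates (a mean, or a min/max
  pair collapsed to its midpoint) are normalized to proportions summing
  to 1. The **proportion of non-foraged food** is the sum of the
  domesticated and purchased/traded shares.
* **Gendered division of food production labour.** Each source carries a
  1–5 score (1 = women only, 5 = men only). The statistic is the
  intake-weighted mean score shifted by 3, giving −2 (women do all food
  production labour) to +2 (men do all), 0 when both genders contribute
  equally.
* **Climate.** From a monthly tmax/tmin/precipitation series, monthly values
  are first averaged over a 30-year window (configurable) ending in the
  last year of data collection; annual mean temperature is the mean of the
  twelve monthly (tmax+tmin)/2 midpoints, annual precipitation the sum of
  the twelve monthly totals.
* **Dangerous mammal density.** Curated species densities are summed; totals
  below 1 n/km² are "low", above 10 "high". The published site totals split
  naturally around this gap, so a total inside [1, 10] has no principled
  class and raises an error demanding an explicit analyst decision rather
  than silently binarizing.
* **Water quality/quantity.** A 4-point scale (1 = enough good water, 4 =
  scarce poor water); rating 3 is accepted by the type for scale
  completeness even though no published site used it.
* **Standardization.** Continuous covariates are z-scored over the set of
  society values (one value per society, sample SD with n−1); both the
  weighting and the denominator are design choices of this package, and
  subset refits restandardize within the retained societies by default
  (switchable). Constant covariates get a zero z-column with a
  warning.

## Estimation

Models are fit by a No-U-Turn sampler implemented in the package
(`mmbm.nuts`), consuming the exact unconstrained log posterior and analytic
gradient defined in `mmbm.core`. The default plan is 3 chains × 2000
iterations with the first half discarded as warmup; per-chain seeds derive
deterministically from one master seed, so a fit is exactly reproducible.

The posterior geometry of this model class is awkward in three specific
ways, and the sampler addresses each:

1. **Fixed effects ride ridges with the latent innovations.** In the
   non-centered parameterization, β_k and the design-aligned components of
   the individual innovations are strongly negatively correlated. The
   individual-innovation block is therefore rotated by an orthogonal matrix
   whose leading directions span the design columns (the standard-normal
   prior is rotation invariant), and those components join a **dense mass
   matrix block** together with β, log σ, the correlation parameters, and
   the society innovations; the remaining coordinates keep a diagonal
   metric. The dense block is estimated from pooled warmup draws with
   Ledoit–Wolf shrinkage at the final adaptation window; earlier windows
   use diagonal scaling (Stan-style expanding schedule with dual-averaging
   step-size adaptation towards acceptance 0.9).
2. **Scales and correlations ride a ridge with their innovations.** After
   every NUTS iteration an ancillarity–sufficiency interweaving move
   resamples (σ, R) from their exact conditional given the realized random
   effects ν (a cheap 4×4 computation — given ν the likelihood is flat in
   (σ, R)), then back-solves the innovations. Coordinate-wise slice
   sampling makes the move tuning-free.
3. **Python overhead.** The log-posterior/gradient kernel and the
   interweaving conditional are numba-compiled (≈20 µs per gradient at the
   recovery-test scale); a pure-numpy reference path computes the same
   quantities and the test suite asserts their equality to 1e-9.

Divergences are counted post-warmup with the conventional energy-error
threshold of 1000.

## Convergence rule

Convergence is declared when all monitored split R-hats are below 1.01 and
no post-warmup iteration diverged. R-hat is the classic split Gelman–Rubin
statistic (the diagnostic of the rstan/rethinking tradition this model
class comes from); the stricter rank-normalized variant is available as
`rhat(..., method="rank")`.

The monitored set is a deliberate choice. By default it is the fixed
effects — the coefficients the analysis reports and interprets. R-hats for
the random-effect scales, correlations and society effects are always
computed and reported (and can gate convergence via
`monitor="structural"`), and the maximum over the child-level effects is
reported separately. The child-level latents can never meaningfully gate
an all-parameters rule at desk scale: with a few hundred retained draws,
the maximum split R-hat over hundreds of essentially independent
coordinates exceeds 1.01 by chance alone more often than not — a property
of the statistic, not of the sampler — which we verified by Monte Carlo
with literally independent draws.

## Model comparison and summaries

WAIC is computed from the pointwise log-likelihood draws on the deviance
scale: lppd_i = log mean_s exp(ll_si), p_i = var_s(ll_si),
WAIC = −2 Σ_i (lppd_i − p_i), with a standard error from the pointwise
contributions. Akaike-style weights are exp(−Δ/2) normalized over the
candidate set. Fixed-effect summaries report posterior mean, SD, and
equal-tailed credible intervals (95% for tables with a zero-exclusion flag;
89% for predicted-probability outputs), using linear-interpolation sample
quantiles.

Predicted probabilities for a covariate profile are computed per posterior
draw either with random effects at zero (`median_unit`, the default: a
typical child in a typical society) or averaged over fresh random-effect
draws from the fitted covariance matrices (`marginal`); the published
figures do not state their averaging convention, so both are provided.

## Synthetic data and what it does (not) show

The generator runs the model forward: draw society effects from
Normal(0, Ω_S), child effects from Normal(0, Ω_I), form the linear
predictors from the design, and sample categories. The default design
mirrors the published sample structure: 12 societies with their printed
covariate values and roster sizes (690 children; 52% girls; age classes
≈ 30/45/25%), lognormal observation counts per child moment-matched to
mean 124.05 and SD 160.88 (truncated at 1), and 2.6% dual-coded
observations (expanded to two records at ingestion, matching the analysis
convention of counting each as unique). Default generating fixed effects
are the published individual-level posterior means — a realistic parameter
set; the random-effect scales are not printed anywhere, so σ_I = 0.8 and
σ_S = 0.6 (correlations at identity) were fixed once as values typical of
logit-scale behavioural heterogeneity.

The generator emulates the study's *structure*, not its *content*: real
coding schemes differ by site, real observation counts cluster by
data-collection protocol rather than a lognormal, ages are often known only
as classes, and real covariates are measured with error. Passing recovery
tests therefore demonstrates that the estimation machinery is correct and
calibrated under the model, not that the model is right for any particular
field dataset.

Parameter recovery is tested at a reduced scale chosen to keep a
20-replicate generate→fit experiment on one CPU within minutes: 8 societies
× 15 children × 40 observations, 2 chains × 800 iterations. At this scale
the 95% intervals cover the generating fixed effects in well over 85% of
cases and the monitored R-hat rule holds in ≥ 18/20 replicates.

## Numerical choices and edge cases

* Softmax uses max-subtraction; probabilities sum to 1 within 1e−12 for
  |η| ≤ 30, and the logit/softmax round trip is exact to 1e−10.
* Ages at class boundaries are floored to whole years before
  classification (the class bounds are stated in whole years); labelled
  (Mikea-style) children map early_juvenile→early, late_juvenile→middle,
  young_adult→adolescent with midpoint ages 6.5/12/20.5 used for
  descriptive statistics only.
* Dual-coded observations are duplicated rows with equal weight, not
  ½-weighted; the likelihood treats them as independent observations. This
  mirrors the analysis convention; a fractional-weight sensitivity analysis
  would require an observation-weight feature that is deliberately out of
  scope.
* Children with zero records are excluded from proportion summaries with a
  logged warning, never a division by zero.
* Extreme unconstrained positions (|log σ| > 40, |atanh-correlation| > 18)
  are reported as out of support so the sampler rejects them instead of
  overflowing.
* The fit is a pure function of (data, config, seed); draws serialize to a
  long-format CSV plus a JSON sidecar and round-trip bit-for-bit.

## Known limitations

* No temporal autocorrelation structure is modelled (a deliberate scope
  decision matching the analysis tradition); estimates may be biased where
  within-child sampling is dense in time.
* Schooling is not a separate outcome category; it lives inside "other".
* WAIC's standard error is known to be optimistic for small n; no PSIS-LOO
  alternative is provided (the comparison statistic is WAIC by design).
* The marginal prediction mode integrates over both random-effect levels
  with a finite Monte-Carlo sample per draw (n_mc configurable).
* Reproducing the published coefficient tables requires the original
  behavioural dataset and cluster-scale sampling; the pipeline supports
  that run (Models 1–5, subset refits, CSV ingestion) but the test gate is
  property-based validation on synthetic data.
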