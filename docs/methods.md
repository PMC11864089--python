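# Methods

## Model

The individual-level model is a two-level random-intercept binary logistic
regression: outcome y_ij for respondent i in health region j,

logit P(y_ij = 1 | x_ij, u_j) = x_ij' β + u_j,   u_j ~ N(0, σ_u²).

Fixed effects use reference-cell dummy coding; the reference level is the
first declared level of each categorical variable unless the variable
dictionary names another. Interactions between two terms can be declared
explicitly (`a:b`); no automated interaction screening is performed.

The marginal likelihood integrates u_j out by adaptive Gauss–Hermite
quadrature: per evaluation, each group's posterior mode and curvature are
found by a damped Newton iteration (vectorized over groups), and the
quadrature grid is centered and scaled there. Nine nodes are the default
(one node is exactly the Laplace approximation); on the bundled recovery
design, moving from 9 to 25 nodes changes the converged log-likelihood by
less than 1e-3, which is the basis for the default. The optimizer is
L-BFGS-B over (β, log σ_u) with an analytic gradient (posterior-weighted
score with the adaptive centering held fixed — the neglected terms are of
the order of the quadrature error). σ_u is bounded below at 1e-6 on the
optimization scale; a solution at σ_u ≤ 0.01 is reported with a
`boundary` flag and σ_u effectively 0 rather than as an error. Standard
errors come from the numerical Hessian at the optimum (delta method for
σ_u); at a boundary fit the Hessian is taken over β only.

The σ_u = 0 reference model is an ordinary logistic regression delegated
to statsmodels GLM (Binomial family, IRLS, relative tolerance 1e-10,
at most 100 iterations). Perfect separation is diagnosed explicitly
(diverging coefficients together with error-free classification) and
raised as an error carrying iteration diagnostics. During development the
mixed fitter was checked against an independent implementation of the same
estimator (lme4's `glmer` with nAGQ = 9, driven through Rscript); that
check is retained in the test suite and agrees to ~1e-3 on coefficients
and log-likelihood.

**Survey weights in fitting.** Whether individual-level models of this
kind should be fitted with survey weights is genuinely open; the default
is unweighted fitting, with a pseudo-likelihood option (`use_weights`)
that normalizes weights to mean 1, because information criteria are not
meaningful under raw expansion weights. n in the BIC penalty is the number
of respondents, not the weighted total. k counts the fixed effects plus
one variance parameter for mixed fits (no variance parameter for σ_u = 0
fits).

**Backward selection** removes whole term blocks (all dummies of a
categorical variable together). At each step every single-term removal is
refitted (warm-started from the parent estimates) and the removal that
most decreases the chosen criterion is applied; selection stops when no
removal improves it. Exact ties (within 1e-9) drop the term appearing
later in the declared term order. Level-by-level removal within a
categorical block is deliberately not supported.

## Synthetic estimation

The area profile holds the design-column means of an area's respondents
under design weights: the weighted share of each non-reference categorical
level, the weighted mean of each continuous term, the weighted mean
product for interactions. The synthetic logit applies the coefficients to
the profile with the random intercept set to 0, and the predicted
proportion is 100·expit of it. Setting u = 0 is deliberate:
externally-validated areas (new survey years, areas unseen in fitting)
have no estimated intercept, and using the population-average prediction
keeps the deployed estimator identical everywhere. A `use_blup` option
adds estimated intercepts for development-data areas. Area profiles are
always computed from the dataset being validated (the target year); this
is the natural reading of applying the model to each wave's aggregated
data, and a development-year profile can be supplied instead by passing
that dataset.

**The aggregation (Jensen) gap.** Applying coefficients to *marginal*
area proportions is the method's defining convention, but because expit is
nonlinear it differs from averaging individual predictions,
Σ w_i expit(x_i'β) / Σ w_i. Both estimators are implemented; the marginal
convention is the default output and the individual-aggregation version is
the oracle against which its gap is measured. The gap grows with the
within-area spread of the linear predictor and with curvature of expit at
the working prevalence. In the bundled realistic study (C ≈ 0.8,
prevalence ≈ 18%) the gap is a systematic 3–7 percentage-point shortfall
at the province level; at the low-prevalence outcome (≈ 4%) it is a few
tenths of a point. Users forecasting moderate-prevalence outcomes from
highly discriminating models should prefer the individual-aggregation
estimator whenever respondent-level covariate data for the target
population are available; the marginal convention needs only aggregate
proportions, which is its practical appeal.

**Validation metric.** The reported quantity is the signed difference
predicted − observed on the percent scale (the field's tables call this
the "absolute difference" but retain the sign). Proportions are kept at
full precision internally and rounded to two decimals only at
serialization. Areas with no respondents (or with a missing predictor
making the profile incomputable) are skipped with a logged warning rather
than failing the run.

## Survey estimation and bootstrap variance

Observed proportions are Horvitz–Thompson ratios 100·Σw_iy_i/Σw_i.
Variance uses replicate weights in the mean-bootstrap convention:
sqrt((1/B)·Σ_b (θ_b − θ̂)²) with deviations from the full-sample
(design-weight) estimate, not the replicate mean. The simulator's
replicate weights follow the Rao–Wu–Yue rescaled cluster bootstrap:
within each province stratum, n_h − 1 of its n_h clusters are resampled
with replacement and weights rescaled by (n_h/(n_h−1))·(selection count);
a single-cluster stratum keeps its design weights. No Taylor
linearization and no weight calibration/raking are provided.

## The simulator and what passing tests do (and do not) show

`generate_population` draws, per health region: one random intercept per
outcome from N(0, σ_u²); categorical predictors from region-specific level
probabilities (continuous predictors from normal distributions, standard
normal by default); outcomes from Bernoulli(expit(β₀ + Σβ_jx_j + u));
design weights as lognormal noise normalized to mean 1 within province;
and synthetic dwelling clusters of configurable size (default 10) for the
replicate-weight bootstrap. Identical (config, seed) reproduce the dataset
bit-for-bit.

The bundled study conditions: three waves of 28,600 respondents (a
desk-scale stand-in for a ~65,000-respondent national survey), 10
provinces grouped into Atlantic/Central/Western regions, 29 health
regions, σ_u = 0.3, weight-noise sd 0.5, six categorical predictors (sex,
age group, self-reported mental health, diagnosed mood/anxiety disorder,
life stress, life satisfaction) with province-specific distributions.
Intercepts were solved numerically once so the marginal prevalences equal
the published national figures (≈17.8% perceived, ≈3.8% unmet) and then
frozen in the configs; validation waves drift mildly in two predictor
distributions.

The controlled designs serve specific claims. The *homogeneous-areas*
design (10 areas × 2000, one covariate pattern per area, σ_u = 0)
emulates the low-prevalence outcome (area prevalences ~3–8%): there the
sampling noise of an area (3 SEs ≲ 0.7 pp) sits below the 1-pp agreement
bar, so observed-vs-predicted agreement is informative about the estimator
rather than about binomial noise — at moderate prevalence no estimator
could meet a 1-pp bar at this sample size. The *heterogeneous-areas*
design uses strong effects so the Jensen gap is clearly visible.

What the simulator does not emulate: real sampling frames and multi-stage
selection probabilities, nonresponse and calibration adjustments, item
missingness, measurement error in the outcome instrument, spatial
correlation beyond the region random intercept, and any systematic
year-to-year model drift other than the configured distribution shifts.
Passing tests therefore demonstrate that the estimation chain is correct
under its own assumptions, not that the fitted coefficients or the
published provincial estimates are recoverable from confidential survey
data.

## Numerical conventions and degenerate inputs

* C statistic: weighted concordance with half-credit ties, computed by a
  sort-and-accumulate pass over unique risk values; exactly equals pair
  enumeration (tested on random tied/weighted instances). Undefined for a
  single-class outcome.
* Calibration slope: logistic refit of the outcome on logit(risk);
  requires risks strictly inside (0,1) and non-constant.
* Decile calibration: groups are weighted tenths of the risk distribution
  with ties broken by row order; group weight shares always sum to 1.
* Proportions are carried on the percent scale throughout.
* All package errors derive from one base class, with configuration,
  schema, estimation, specification, design-matrix (naming the collinear
  columns), fit/separation and undefined-metric subclasses.

## Problem sizes

Defaults were chosen so the complete test suite and the acceptance script
each run in minutes on one CPU: waves of ~28,600 respondents, recovery
design 30 × 500, controlled designs 10 × 2000, 20-replicate selection
experiment at n = 10,000, B = 100–200 bootstrap replicates. All are
configurable upward.
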