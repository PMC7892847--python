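# Methods

This note documents the models implemented in `salmon-lcm`, the default
parameter values and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that a user
extending the package should know about.

## Environmental covariate process

All life stages are forced by a shared vector of annual covariates
modelled as a stationary first-order multivariate autoregression around
its mean: `x_t ~ MVN(rho * x_{t-1}, Q)` with a single scalar `rho` and an
unstructured (fully free) covariance `Q`; observations add a fixed,
negligible noise (sd 0.001), i.e. covariates are treated as measured
without error.  For `n` covariates the model carries `0.5 n (n-1)` free
correlation parameters, which is the point: marine and freshwater drivers
are allowed arbitrary cross-correlation so that climate forcing hits
multiple life stages coherently.

**Estimator.** Because the observation noise is fixed three orders of
magnitude below the process scale, the fit maximizes the conditional
likelihood of the AR(1) with observations standing in for latent states:
given `rho`, the innovation covariance has the closed form
`Q(rho) = (1/(T-1)) Σ (x_t - rho x_{t-1})(x_t - rho x_{t-1})'`, and the
profile likelihood is optimized over `rho` alone (bounded scalar search,
tolerance 1e-10).  A per-covariate (diagonal) `rho` variant is available
behind `per_covariate_rho=True`; the scalar form is the default.
Recovery from a 3000-year simulation is within ±0.05 on `rho` and every
pairwise correlation (tested).  Constant or collinear covariates produce a
`SingularCovarianceError` suggesting regularization rather than a silent
near-singular fit.

Strictly positive covariates (flows on a physical scale) can be fit and
simulated on the log scale via `log_covariates`; the default synthetic
world works on standardized anomalies (mean 0, sd 1), where positivity is
not a concern, so the flag defaults to off there.

**Simulation.** Detrended draws start from the stationary distribution
(`V = Q / (1 - rho_i rho_j)` elementwise) and recurse; draws are seeded
and bit-reproducible.

## Climate-change scenarios

Trends are extracted from GCM ensembles in four steps, per member: mean
over a baseline window (2005–2025, centered on 2015); anomalies from that
mean; a centered running mean of the anomalies; then per-year
25th/50th/75th percentiles across members (linear-interpolation
quantiles).  The "20-year" running mean is implemented as a symmetric
window of half-width `window // 2` (21 points interior, truncated at the
series edges): an exactly centered window preserves linear trends
identically at interior years, which the round-trip test requires, and
even-length windows cannot be centered.  Scenario forcing is additive:
`forced = detrended draw + offsets`, leaving the variance and
autocorrelation of the stationary component untouched.  Temperature and
flow trends are treated as independent across covariates.

## Stage models

**Gompertz stock–recruitment** (both freshwater stages):
`log R = a + (1+b) log S + Σ c_i x_i + eps`, `eps ~ N(0, sigma_proc²)`.
`a` is log productivity, `b < 0` compensation (capacity `exp(-a/b)`), and
zero stock is absorbing.  Fitting is ordinary least squares on the log
scale; designs with condition number above 1e8 are rejected as collinear.
Multi-population fitting offers partial pooling by precision-weighted
shrinkage toward the grand mean with DerSimonian–Laird between-population
variance — a deterministic, desk-scale stand-in for a hierarchical MCMC
fit with equivalent point behaviour, validated by simulate-then-refit
coverage tests.

**Mainstem passage** is an emulator, not a hydraulic model: a table of
(survival, arrival-day shift, transported fraction) records binned by
annual spring mean temperature and flow, sampled uniformly within the bin
containing the year's conditions.  Out-of-range conditions clamp to the
nearest bin; empty bins fall back to the nearest occupied bin.  The
deterministic mode uses bin means.

**Transport rule**: barge transport has a fixed calendar window
(default days 100–160); fish arriving inside it are transported with a
configured probability, outside it never.

**Smolt-to-adult return (SAR)** is logistic in environmental covariates
with AR(1) random effects of ocean-entry day and a day-by-year
interaction, fit separately for transported and in-river fish.  Fitting
uses a Laplace approximation: fixed and random effects are jointly
maximized by damped Newton steps for each candidate variance vector, with
the AR(1) prior precision tridiagonal (log-determinant in closed form),
and the variance components maximize a REML-type marginal likelihood that
integrates the fixed effects out as well — without that correction the
year-level variance, and with it every fixed-effect standard error for
year-resolved covariates, is biased low.  The day-by-year AR(1) term is
not estimated directly; a year-level random intercept absorbs it at the
cohort level (the environmental covariates vary only by year, so this is
the level at which it matters), and its full AR(1) structure is simulated
from template parameters in projection mode.  In projection the cohort is
represented by its mean entry day, so day effects are evaluated at one day
per year and drawn from their stationary marginal
`N(0, day_sd² + dayyear_sd²)` — exact for a single evaluation point.

**Maturation partition.**  Total SAR is decomposed as
`S_SAR = S3 (b3 + (1-b3) S0 (b4 + (1-b4) S0))`, giving age fractions
`N3/N2 = S3`, `N4/N2 = (1-b3) S3 S0`, `N5/N2 = (1-b4)(1-b3) S3 S0²`.
The round trip through `sar_from_ages` is an algebraic identity, tested to
1e-12 across the valid domain.  Parameter sets implying `S3 > 1` are
flagged implausible (calibration rejects them with infinite deviance)
rather than clipped.  Age-6 returns are pooled with age 5.

**Upstream survival** is a logistic-linear stand-in with configured
coefficients — the life cycle only needs a monotone covariate-to-survival
map — and prespawn survival is a constant (default 0.9).

## Life-cycle projection

Brood-year alignment: spawners in fall of year t produce parr exposed to
year t+1 rearing covariates; smolts migrate in spring t+2; jacks return at
t+3, age-4 adults at t+4, age-5 at t+5.  Effective spawners weight ages
3/4/5 by 0/1/F5.  Transitions apply to expected (continuous) abundances
with lognormal process noise where fitted, matching the fitted
process-error structure; demographic (binomial) sampling is deliberately
not the default.

The first five projection years are pinned to the initial abundance while
the age structure spins up; model-generated returns take over from year
six.  The vectorized kernel (`simulate_ensemble`) pre-draws every
stochastic input in a fixed order — process deviates, day effects,
mainstem record uniforms — so two scenario cells run with the same seed
differ only through the forced stage's inputs (common random numbers).
`step_year` is the scalar reference implementation of the same algebra and
the two are cross-checked against an independent hand recursion in the
tests.  Iteration i of a projection pairs with detrended draw i.

## ABC calibration

Candidates pair one freshwater-posterior draw, kept intact to preserve its
internal correlations, with independent tuning-parameter draws: beta
priors (parameterized by mean and concentration, default concentration 10)
for S0, b3, b4 and a normal(mean, 0.1) prior for F5.  Each candidate runs
the life cycle once against the historical covariate record; the deviance
is the two-sample Kolmogorov–Smirnov statistic between the simulated and
observed annual spawner distributions (years pooled).  The spin-up years
are excluded from both samples — they are pinned to the initial abundance
and carry no parameter information.  The top fraction (0.2% of 500,000 at
full scale → exactly 1000 sets) is retained with stable index-order tie
breaking; retained sets with KS p ≤ 0.05 are flagged, never dropped.  An
optional joint mode would add the smolt series; spawners-only is the
default distance.  The orchestrated experiment (`run_experiment`) projects
each population with the component-wise median of its retained maturation
parameters — a point summary chosen for determinism; projecting under
every retained set is available by looping the library calls.

Identifiability caveat: the spawner level identifies the composite
per-smolt spawner multiplier more strongly than any single maturation
parameter, so marginal posteriors contract moderately (tested: retained
IQR below prior IQR on average across replicates, truth inside the
retained 90% interval).

## Risk and sensitivity

QET50 first passage is the final year of the first trailing 4-year window
whose mean spawner count is strictly below 50 ("drops below" read as
strict; a centered-window variant is available).  Decadal abundance is the
geometric mean with a +1 offset inside the log so zero counts stay finite
(offset 0 available for positive series).  The stage-forcing factorial
applies the median RCP 8.5 trend to one stage at a time, detrended
elsewhere, under common random numbers, and reports the 2060s/2020s
geometric-mean ratio per simulation (median and IQR across simulations);
means are geometric throughout for consistency.  Covariate-model variants
(Models 1–3) rewire the tributary and SAR coefficient blocks only.

## Synthetic world defaults

The default study system has 8 populations, 8 covariates on a
standardized-anomaly scale, and 16 historical years.  Equilibrium spawner
abundances span roughly 45–600 across populations (log-productivity
offsets), mirroring the scale of small wild interior-basin populations.
Key defaults: Gompertz stage 1 `a ≈ 7.85 ± pop offset, b = -0.25,
sigma = 0.25`; stage 2 `a = 3.3, b = -0.4, sigma = 0.3` with Model-1
covariates (summer air temperature −0.12, fall flow +0.1); SAR intercepts
−3.9/−3.7 (≈2% return), negative SST coefficients (−0.2 to −0.35),
day effects sd 0.3 (AR 0.9) and day-by-year sd 0.2 (AR 0.8); maturation
truth S0 = 0.7, b3 = 0.1, b4 = 0.6, F5 = 1.1; upstream intercept 2.0 with
spring-temperature coefficient −0.3; prespawn 0.9.  Calibration priors are
deliberately centered away from the truth (0.6 / 0.15 / 0.5 / 1.0) so
posterior contraction is a real test, not an echo of the prior.  GCM trend
magnitudes reached in 2089 default to ≈ +2 sd for temperature covariates
under RCP 8.5 and roughly half that under RCP 4.5, with a leveling
(tanh) shape available for the latter.

What the generators do **not** emulate: detection probability and tag-file
structure of real tagging databases, non-stationary covariance, nonlinear
(threshold) survival responses, metapopulation dispersal, harvest policy,
and ocean acidification.  Passing tests therefore demonstrate that the
estimators and the pipeline machinery are correct under the stated
generating model, not that the defaults describe any real population.

## Problem sizes and numerical choices

The test and acceptance workloads use scaled problem sizes chosen as
sensible desk-scale designs: covariance recovery at 3000 simulated years;
calibration recovery over 20 replicated worlds at 3000 candidates (4%
retention → 100 sets); SAR recovery on 100,000 tagged fish over 16 years;
scenario contrasts and the stage factorial at 200 iterations; full-scale
ABC (500,000 candidates, 0.2%) in the acceptance script.  All randomness
descends from one master seed through named, hash-derived substreams, so
adding a consumer never perturbs existing streams.  CSV writers use
17-significant-digit floats and readers round-trip parsing, so generated
inputs re-read bit-identically.

Known limitations: the ABC distance compares pooled annual distributions,
so it is insensitive to the time ordering of spawner counts; the
maturation parameters are only partially identified (see above); the
Laplace/REML SAR fit, like any GLMM approximation, can underestimate
variance components when the number of years is small; and the
mainstem emulator inherits whatever biases exist in the table used to
build it.
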