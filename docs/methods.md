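# Methods

This note records the statistical procedures implemented in `regstand`,
the numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the limitations a user should know about.

## Estimands and estimators

For a binary outcome Y, exposure X and confounder set Z sufficient for
confounding control, the counterfactual probability under an intervention
setting X = x is p(Y_x = 1) = E_Z{p(Y = 1 | X = x, Z)}. The estimator is
the plug-in average of conditional predictions from a fitted logistic
model over the empirical distribution of Z in a *standardization set* S:

    θ̂_x = (1/|S|) Σ_{i∈S} p̂(Y = 1 | X = x, Z_i).

S defaults to the full estimation sample; restricting it (e.g. to the
factually untreated) estimates subset counterfactuals such as
p(Y₁ = 1 | X = 0), which the number needed to treat requires. The level
sentinel `FACTUAL` leaves each row's exposure untouched. Note that
`FACTUAL` within a subset estimates p(Y = 1 | subset), not the
whole-population prevalence; when the subset is defined by the exposure
itself and the exposure is a main effect of the model, the score equations
make this estimate equal the subset's empirical prevalence exactly.

Counterfactual predictions are produced by rewriting the exposure column
and rebuilding the entire design matrix from the recorded construction
rules, so every exposure-dependent column — main effect, dummy expansion,
interactions, transforms — is recomputed consistently. Unseen categorical
levels are rejected.

For time-to-event outcomes, the conditional event probability comes from a
Cox proportional-hazards model with the Breslow baseline cumulative
hazard: F̂(t | x, Z_i) = 1 − exp{−Λ̂₀(t) exp(z_i(x)ᵀβ̂)}. Standardization
proceeds identically at each requested time point; results are reported in
the survival orientation (1 − θ̂) with one variance matrix per time point.

## Model fitting

*Logistic*: fitting is delegated to the iteratively-reweighted
least-squares implementation in statsmodels (Binomial family, deviance
tolerance 1e-10, at most 100 iterations; non-convergence is an error).
Per-observation scores x_i(y_i − p̂_i) and the inverse observed information
("bread") are recomputed from β̂ inside the package so that variance
construction never depends on backend internals. Fitted probabilities
numerically at 0 or 1 raise a separation error. Rows with missing values
in referenced columns are dropped with a logged count. Categoricals use
reference (treatment) coding with the first sorted observed level as
reference, frozen at fit time for reproducibility. The inverse link
appears in exactly one function, so other links remain addable.

*Cox*: the partial likelihood is maximized by Newton–Raphson with
step-halving (relative log-likelihood tolerance 1e-10, at most 100
iterations), supporting Efron (default, matching common software defaults)
and Breslow tie handling; the tie method used is logged. The gradient and
observed information are computed by vectorized reverse cumulative sums
over the risk sets, with an exact per-tie-group Efron correction. The
baseline cumulative hazard always uses the Breslow estimator at β̂,
regardless of the tie method, as a right-continuous step function:
predictions at t equal to an event time include that event's increment,
and the hazard is held flat beyond the last event time (standardization
beyond the last observed follow-up logs an extrapolation warning).
Coefficients are cross-checked in the test suite against lifelines and
scikit-survival.

## Variance estimation

The joint variance of (θ̂_x) across levels is the sandwich of the stacked
estimating equations: the model score equations together with, for each
level x, Σ_{i∈S} {p(Y=1|X=x,Z_i;β) − θ_x} = 0. The bread is the analytic
derivative of the stacked system (the standardization rows differentiate
to the averaged prediction gradient, which the tests verify against
central differences at relative tolerance 1e-4); the meat is the outer
product of per-unit contributions, where a unit is a cluster when a
cluster identifier is supplied (contributions summed within cluster) and a
row otherwise. Singleton clusters reproduce the unclustered variance
exactly. When standardization runs over a dataset that is not the fit
sample, the two samples' contributions are treated as independent; the
cluster correction is only defined over the fit sample.

For the Cox engine the same M-estimation algebra is organized through
influence functions, because the Breslow baseline is an infinite-
dimensional nuisance: the influence of θ̂_x(t) decomposes into (a) the
averaging residual over S, (b) the β̂-influence (inverse information times
score residual) through the analytic gradient of the standardization
equation, and (c) the influence of the Breslow estimator Λ̂₀(t), which
carries both a martingale-residual term and its own β̂ term. Per-time
variance matrices are produced; cross-time covariances are deliberately
not computed, so all time-indexed inference is pointwise. Score residuals
use the Breslow form evaluated at the fitted coefficients; with continuous
event times (as produced by the generators) the difference from exact
Efron residuals is negligible, and the test suite verifies the resulting
standard errors against a nonparametric bootstrap at 10% tolerance.

A (cluster-)bootstrap variance engine is available on both model classes
(`fit(variance="bootstrap", n_boot=..., seed=...)`) as a fallback and as
an independent check; it resamples rows (or whole clusters), refits and
restandardizes, reusing frozen design matrices so categorical codings
cannot drift across replicates.

## Effect measures and intervals

Contrasts consume event probabilities; survival results store survival
probabilities, and the conversion p = 1 − surv happens in exactly one
place (`estimate_effect`) to prevent double-flipping. Delta-method
variances use analytic gradients (verified against numeric ones by
property tests). Confidence intervals are Wald intervals with the normal
quantile at the requested level (1.959964 at 95%, not a hard-coded 1.96);
the default scale is identity for AF, RERI, risk difference and risk
ratio, and log for the NNT — the log interval exp[log g ± z·se/g] is
always strictly positive. A non-positive risk difference makes the NNT
infinite or negative; the estimate is returned with a structured warning
(falling back to the identity scale) rather than raising, so that
time-curves with crossing survival functions do not abort. Requesting a
log interval for a non-positive estimate of any other measure is an error
that suggests the identity scale. Time-indexed measures get pointwise
intervals only; no simultaneous bands are attempted.

## Synthetic data generators

`generate_binary` emulates a clustered perinatal design: ~190 mothers with
1–5 births each (~500 rows), a 3-level categorical and a continuous
confounder shared within mothers, a binary exposure assigned by a logistic
model in the confounders (prevalence ≈ 0.4), and a logistic outcome model
(prevalence ≈ 0.3) with an optional exposure-by-category product term and
a mother-level normal random intercept (SD 0.5 on the log-odds scale —
a moderate, realistic degree of within-family dependence; any exchangeable
within-cluster dependence suffices to exercise the cluster-robust
variance). With a logistic-normal mixture the marginal conditional law is
very nearly logistic with attenuated coefficients, so the fitted marginal
model is effectively correctly specified; the residual approximation error
is an order of magnitude below the sampling tolerances used in the tests.

`generate_survival` emulates a breast-cancer-like cohort of 3000 patients:
age, a menopause indicator tied to age, a 3-level size category, a Poisson
node count entering the hazard through the decaying transform
exp(−0.12·nodes), treatment assigned by a logistic model (≈ a quarter
treated, preferentially younger and more node-positive patients), a
Weibull baseline hazard (shape 1.2, scale 90 months) and uniform censoring
on 12–120 months. The observed event fraction is logged at generation.

What the generators do **not** emulate: informative or administrative-only
censoring, competing risks, time-varying covariates or effects,
non-proportional hazards, measurement error, and real-data quirks such as
heaped or rounded follow-up times (ties are therefore rare in generated
data). Passing tests demonstrate correctness of the estimators under the
assumed models, not robustness to these violations.

`true_estimands` computes the generative-law values of every reported
estimand by Monte-Carlo integration over the covariate law (default 10⁶
draws, own seed), splitting the draws into 20 batches to attach a
Monte-Carlo standard error to each value; recovery tests use 3 combined
(sampling ⊕ Monte-Carlo) standard errors as tolerance. The NNT truth is
defined among the factually exposed/untreated by weighting with the
assignment model; the RERI truth takes the exposure and the second
categorical level as the two interacting exposures on the population
restricted to the first two categorical levels, mirroring the estimation
recipe (joint four-level recode, levels "00", "01", "10", "11").

## Problem sizes used in the checks

The statistical acceptance tests run at the sizes their claims are stated
for: bootstrap agreement with 2000 replicates (200 clusters × 3 for the
clustered case, n = 2000 independent rows for AF/NNT; the Cox comparison
uses 600 replicates at n = 900), estimand recovery at n = 5000, and
interval coverage over 1000 replicates at n = 1000. The acceptance script
runs the generators at their default sizes (≈ 500 clustered births and
3000 patients), which are the designs the package is built around.

## Known limitations

- Only the logit link is implemented for binary outcomes (the architecture
  isolates the inverse link, so probit and others are addable); no
  regularized or Bayesian fitting.
- Cox: no time-varying covariates, stratified baselines, left truncation
  or competing risks; standardization only over the empirical confounder
  distribution (no external standard population, no IPW or doubly-robust
  estimators).
- Clustered data are handled by variance correction only; estimates remain
  the ordinary MLE plug-ins (no shared-frailty or mixed-model
  standardization).
- The subset expression language is intentionally limited to column
  comparisons combined with `&`/`and` (pandas `eval` syntax).
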