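# Methods

This note documents the models, the estimation choices, the synthetic-data
generator, and the limitations a user should know before trusting the
output on real data.

## Data model

The unit of analysis is one record per subject (or per implant when the
implant-level expansion is used): an interval `(entry, exit]` in days from
implant insertion, a binary event indicator (any complication — implant
loss, peri-implantitis or technical — pooled as one event type), a cluster
identifier (the patient), and categorical covariates described by an
ordered level list with a designated reference level per category.  Records
with a missing modelled covariate are dropped with a logged report; no
imputation.  The design matrix has one 0/1 dummy per non-reference level,
ordered by category then level, so the implant covariate set (periodontal
status 3, extent of treatment 3, age group 4, sex 2, ever-smoker 2, product
4, retention 3 levels) yields 14 columns.  Analysis is single-failure: each
record contributes at most one event.

## Descriptives

Incidence rate is events divided by summed at-risk time (exit − entry),
reported to 6 decimals.  The Kaplan–Meier estimator handles delayed entry;
at tied times events precede censorings (censored records stay in the risk
set at their exit time).  Survival quantiles use the step-function
convention — the q-quantile is the smallest observed *event* time with
S(t) ≤ 1 − q, without interpolation — and quantiles the curve never reaches
are reported with the `cbc` ("cannot be computed") sentinel rather than a
number.

## Cox model with shared gamma frailty

Estimation is Breslow-form partial likelihood over ordered failure times;
ties use the Breslow approximation (the likelihood is evaluated exactly in
the form written, no Efron correction).  Newton–Raphson with step halving,
gradient tolerance 1e-8, 100-iteration cap; covariate columns with zero
variance are excluded with a warning and a flagged zero coefficient.
Stratified fits sum the partial likelihood over strata.

The shared gamma frailty (mean 1, variance θ) is profiled: for fixed θ the
log frailties `v_i` and β maximise the penalised partial likelihood with
penalty `Σ_i (v_i − e^{v_i})/θ`, solved by an EM-type alternation — Cox
Newton step with cluster offsets, then the closed-form frailty update
`e^{v_i} = (1/θ + D_i)/(1/θ + C_i)` with `D_i` the cluster's events and
`C_i` its accumulated relative-risk-weighted baseline hazard (evaluated as
an exact step function, not interpolated).  The profile objective adds the
gamma normalising terms, written with `expm1`/`log1p` and the telescoped
gamma ratio `Π_{j<D}(1 + jθ)` so it stays accurate as θ → 0, and a bounded
one-dimensional search over `ln θ ∈ [ln 1e-8, ln 10]` (tolerance 1e-6)
yields the MLE; a boundary estimate at the cap is warned about.  The
reported β covariance conditions on the estimated frailties (penalised
curvature): with hundreds of clusters the full joint information is
impractical to invert routinely, and the approximation slightly understates
frailty-induced uncertainty — a known trade-off for this estimator.

The proportional-hazards check is the score test for a linear-in-time
interaction of each coefficient, built from Schoenfeld residuals with exact
per-event risk-set variances (identity time transform, centered and scaled
for conditioning; the statistic is transform-scale invariant).  Its degrees
of freedom equal the number of columns tested; a column subset can be
passed explicitly.  Simulated type-I error at α = 0.05 is 0.050 over 500
proportional-hazards replicates (see the acceptance suite).

## Parametric families

Exponential and Weibull come in PH (`H = λt^γ e^{xβ}`) and AFT forms;
log-logistic, log-normal and generalized gamma are AFT-only.  "Gamma" means
the three-parameter generalized gamma in its positive-shape branch
(`(t/e^{μ+xβ})^{1/σ} ~ Gamma(a)`), which covers Weibull (a = 1), gamma
(σ = 1/…) and approaches the log-normal in the interior.  Ancillary
parameters are estimated on the log scale.  The censored log-likelihood is
`Σ d log f + (1−d) log S`; delayed entry conditions on survival to the
entry time (frailty-free fits only — the generator's cohorts all enter at
t = 0, and frailty with truncation is rejected with a clear error).

Cluster random effects: PH families use the multiplicative mean-1 gamma
frailty with the closed-form cluster marginal

    Π_i h_i^{d_i} · Π_{j<D}(1+jθ) / (1 + θ Σ_i H_i)^{1/θ + D},

avoiding quadrature error entirely; AFT families use a normal random
intercept on log time marginalised by 15-node Gauss–Hermite quadrature
(non-adaptive: cluster sizes here are ≤ 12 and the likelihood is
well-scaled, where plain GH agrees with direct numeric integration to
~1e-6 — tested).  Optimisation is L-BFGS-B with a Nelder–Mead polish;
covariance from a central-difference Hessian.

## Flexible parametric (spline) model

The log cumulative hazard is `η(t,x) = s(ln t; γ) + xβ` with `s` a
restricted cubic spline: `df` terms, `df − 1` internal knots at centiles
`100·j/df` of the uncensored log event times (linear-interpolation sample
quantiles), boundary knots at their min and max, truncated-cube basis with
linear tails and continuous second derivatives.  The df convention is
"terms on log time": df = internal knots + 1, so df = 1 has no internal
knots and is exactly Weibull PH (γ₀, γ₁ are log-scale and shape).  df is
capped at 9.  The full spline design (including the intercept) is
orthogonalised by Gram–Schmidt (QR) over the uncensored log event times;
the invertible transform is stored, predictions are invariant to it
(tested to 1e-6 on the log-likelihood), and the reported `_rcs` slopes live
on the orthogonalised scale.

The record log-likelihood is `d(ln s′(ln t) + η − ln t) − e^η` (the
`−d ln t` Jacobian is included so values are directly comparable with the
parametric families), and the shared-gamma-frailty variant uses the same
closed-form cluster marginal with `H = e^η`.  Estimation: L-BFGS-B on
(γ, β, ln θ) with analytic gradients, warm-started from a projected
exponential fit, ln θ bounded in [ln 1e-8, ln 10].  When the quasi-Newton
line search stalls (typically on the flat ln θ direction as θ → 0), a
damped-Newton polish on the exact gradient finishes the job; convergence is
declared when the residual Newton displacement is below 1e-3 — two orders
of magnitude under any standard error in the test conditions.  Monotonicity
of the fitted `ln H` is *not* enforced during optimisation; `s′ ≤ 0` at an
event time is handled by a smooth log-barrier extension during search and
diagnosed with a warning at the optimum.  Standard errors come from the
observed information (central differences of the analytic gradient); the θ
interval is Wald on the log scale.

The df ladder warm-starts each df from the least-squares projection of the
previous fit's spline and retries from the default start if the
log-likelihood drops.  One genuine property of centile-placed knots is
worth stating plainly: **bases at different df are not nested** (only the
df = 1 linear spline is contained in all), so the maximised log-likelihood
can decrease slightly (≲ 0.5) from one df to the next even at the exact
optimum — confirmed by multi-start optimisation.  On Weibull-truth data the
ladder is monotone in practice and the spread across df ∈ [2, 6] is well
under 1%.

## Model comparison and selection

`AIC = −2ℓ + 2k` and `BIC = −2ℓ + k ln N` with k the number of freely
estimated parameters (coefficients + ancillary + spline terms + frailty
variance).  N is an explicit, logged setting defaulting to the number of
analysis records: BIC is not invariant to how observations are counted in
clustered data, so the choice is surfaced rather than hidden.  Cox rows use
the partial likelihood; comparing it with full likelihoods on one table
follows the comparison-protocol convention this package implements, but the
two are not on a common scale — flexible-vs-parametric comparisons within
the full-likelihood block are the meaningful ones.  Selection: rows whose
spline slopes are not all significant at 5% are screened out (unless that
removes everything), the minimum-BIC survivor wins, and AIC near-ties among
flexible fits (relative difference < 0.1%) are recorded in the rationale in
favour of the simplest df.

## Synthetic cohorts

The generator draws, per patient: covariate levels independently from
configured margins (defaults: the reference cohort's frequencies),
a gamma(mean 1, variance θ) frailty (default θ = 0.5 for frailty
scenarios), and event times by inverting
`S(t|x,α) = exp(−α H₀(t) e^{xβ})` with uniform draws; administrative
censoring at 3287 days (~9 years), optional uniform early dropout
(default off).  Default effect sizes are the published adjusted hazard
ratios, so recovery studies target the published scale.  Default cohort
size is 595 patients; the implant-level expansion draws
round-normal(4.0, 2.8) implants per patient truncated to [1, 12], sharing
the patient's covariates and frailty, with the patient as cluster.

The default Weibull baseline (λ = 7.7235e-07, γ = 1.6196) was calibrated
once by least squares on the relative errors of two targets — overall
incidence 0.000241/day and median 2476 days.  The pair is not exactly
attainable together: once person-time stops at the first event, any
baseline matching that median implies a rate of at least ~0.00027/day under
the default margins and θ; the compromise lands within ~7% of each target
(rate 0.000257, median 2649).  `calibrate_baseline` solves a feasible
(rate, median) pair exactly — the median condition pins λ for each shape
through the closed-form frailty-marginal survival averaged over a fixed
covariate sample, and root-finding on the shape matches the incidence —
and raises an error quoting the achievable range for an infeasible pair.

For selection-behaviour studies, `df2_spline_truth()` provides a fixed
one-knot spline baseline (knots 4.0/6.5/8.1 on ln-days, coefficients
−17.3/2.5/0.175): clearly non-Weibull, decelerating hazard, ~60% events by
the horizon at default margins.  Its cumulative hazard is inverted by
vectorised bisection.

What the generator does *not* emulate: dependence between covariates
(edentulous patients necessarily carrying full-jaw restorations, say —
categories are drawn independently, with the margins hook available for a
user-supplied joint table); the three complication subtypes (pooled, as in
the analysis the package implements); recurrent events per implant; and
non-administrative loss to follow-up patterns.  Passing recovery tests
therefore demonstrates correctness of the estimators under the assumed
model, not robustness to real-data violations of it.

## Problem sizes used by the test and acceptance suites

Chosen as the package's own study conditions: recovery at 200 replicates of
595 patient clusters with implant-level records (θ = 0.5, published effect
sizes); type-I-error of the PH test over 500 replicates of 200-subject
two-covariate cohorts; selection behaviour over 100 seeds of 250-cluster
spline-truth cohorts with a df ∈ {1,2,3} × {frailty, no frailty} grid;
oracle fixtures of 8–200 records.  Observed behaviour at those sizes:
θ coverage ≈ 0.96, β coverage ≈ 0.93, mean θ̂ ≈ 0.47 under θ = 0.5; mean
θ̂ < 0.01 under θ = 0; PH rejection rate 0.050.

## Known limitations

* Cox frailty β standard errors condition on the estimated frailties
  (slightly anti-conservative).
* Breslow ties only; with heavy ties Efron would be preferable.
* The AFT random intercept uses non-adaptive Gauss–Hermite; very large
  clusters or variances would warrant adaptive centering.
* Delayed entry is supported only without frailty.
* The df ladder's log-likelihood is not mathematically monotone across
  centile-knot bases (see above); decisions should rest on AIC/BIC and
  slope significance, which is what `select_best` does.
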