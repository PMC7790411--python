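# implantsurv

Survival models for clustered dental-implant complication data.

## The problem

Implant-supported dental restorations fail in several ways — implant loss,
peri-implantitis, technical complications — and a patient typically carries
several implants.  Events within one patient are correlated: the patient's
teeth form a cluster, and an unobserved patient-level susceptibility
(**frailty**) multiplies every hazard in the cluster.  Ignoring that
clustering biases effect estimates and understates uncertainty.  This package
implements, and lets you compare on equal terms, the ladder of time-to-event
models used for such cohorts:

* **Cox proportional hazards** — Breslow partial likelihood over risk sets,
  with an optional **shared gamma frailty** (mean 1, variance θ) estimated by
  profile likelihood, and a Schoenfeld-residual score test of the
  proportional-hazards assumption;
* **parametric PH/AFT families** — exponential, Weibull (both PH and AFT),
  log-logistic, log-normal and generalized gamma (AFT), with gamma frailty
  (PH, closed-form cluster marginal) or a normal random intercept on log time
  (AFT, Gauss–Hermite quadrature);
* **flexible parametric (spline) models** — the log cumulative hazard is a
  restricted cubic spline in log time,

      ln H(t | x) = s(ln t; γ) + xβ,

  with `df` spline terms, internal knots at centiles `100·j/df` of the
  uncensored log event times, boundary knots at their extremes, and optional
  shared gamma frailty.  `df = 1` is exactly the Weibull PH model
  (`ln H = ln λ + γ ln t + xβ`);
* **model selection** — log-likelihood, `AIC = −2ℓ + 2k` and
  `BIC = −2ℓ + k ln N` across the whole grid, with the decision rule: minimum
  BIC among models whose every spline slope is significant, preferring the
  simplest spline model when AICs are near-tied.

Because the motivating cohort (595 Swedish patients followed ~9 years, 469
first complications, overall incidence 0.000241/day) is not publicly
deposited, the package ships a **seeded synthetic-cohort generator** that
emulates its structure — covariate margins, published adjusted hazard
ratios, cluster sizes (mean 4 implants/patient), administrative censoring,
and a Weibull baseline calibrated to the published incidence and median
survival — so every estimator is exercised by parameter-recovery and
calibration tests rather than by a private dataset.

## Worked example

```python
import implantsurv as im

cfg = im.SyntheticConfig(seed=1, implant_level=True, frailty_theta=0.5)
cohort, truth = im.generate(cfg)
print(f"records: {len(cohort)}  events: {cohort.n_events}  clusters: {cohort.n_clusters}")
rate = im.incidence_rate(cohort.n_events, cohort.person_time)
print(f"incidence rate: {rate.rate:.6f} per day")

fit = im.fit_rp(cohort, df=2, frailty=True)     # spline model, gamma frailty
print(f"loglik: {fit.loglik:.2f}   theta: {fit.theta:.3f}")
print(fit.beta_summary().head(4).round(3).to_string(index=False))
print(fit.spline_summary().round(3).to_string(index=False))
```

prints

```
records: 2577  events: 1548  clusters: 595
incidence rate: 0.000262 per day
loglik: -13889.09   theta: 0.505
                     term  coef    hr  hr_low  hr_high     p
periodontal=Periodontitis 0.494 1.639   1.346    1.996 0.000
     periodontal=No teeth 0.175 1.191   0.932    1.522 0.163
          extent=Full jaw 1.471 4.353   3.417    5.546 0.000
       extent=Partial jaw 0.748 2.113   1.693    2.638 0.000
 term  coef  ratio  ratio_low  ratio_high     p
_rcs1 1.208  3.345      3.129       3.577 0.000
_rcs2 0.008  1.008      0.967       1.051 0.697
```

Reading the output: the cohort was generated with frailty variance θ = 0.5
and the profile estimate is 0.505; the fitted hazard ratios bracket the
generative ones (periodontitis 1.449, full jaw 4.641, partial jaw 2.338 —
each inside its 95% CI).  The `_rcs` rows are the spline slopes of the log
baseline cumulative hazard on the orthogonalised scale; a non-significant
`_rcs2` correctly signals that this cohort's Weibull truth needs no second
spline term.

The same analysis runs end to end from the shell:

```bash
implantsurv simulate --seed 1 --implant-level --theta 0.5 --out cohort.csv
implantsurv analyze --input cohort.csv --outdir run/     # or omit --input
```

writing `table1.csv` (incidence and quartile survival per covariate level,
with `cbc` for quantiles the KM curve never reaches), `comparison.csv`
(ll/AIC/BIC for the whole model grid), `best_model.csv` (hazard ratios, CIs
and spline terms of the selected model), `ph_test.txt` and tidy
hazard/survival curves under `curves/`.

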