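# hypertabph

Parametric proportional-hazards survival analysis with a **hypertabastic
baseline**, for right-censored time-to-event data with clinical and
gene-expression covariates.

Semi-parametric Cox regression estimates covariate effects without ever
committing to a baseline hazard — which also means it cannot answer
questions about the *shape* of risk over time. When a flexible
parametric family fits the data, one gains explicit survival and hazard
curves and everything that follows from them: when the hazard rises
fastest, when survival falls fastest, survival probabilities at named
horizons, and conditional survival for patients who have already
survived some years. This package implements that programme around the
two-parameter hypertabastic distribution

    S0(t) = sech(α [1 − t^β coth(t^β)] / β),     α, β > 0,

whose hazard can be increasing, decreasing or unimodal. The model for a
subject with covariates x is the proportional-hazards form

    h(t|x) = h0(t) · exp(x'θ),     S(t|x) = S0(t)^exp(x'θ),

fitted by right-censored maximum likelihood, with Wald inference
((θ̂/SE)² against χ²(1)), hazard ratios exp(θ̂), AIC model comparison
against Weibull-PH and log-logistic-PH baselines, forward covariate
selection with a pairwise-correlation screen (|r| < 0.5), dynamic
analysis of the fitted curves, and a synthetic-cohort simulator that
emulates a 295-subject breast-cancer study design (AGE, a binary
seventy-gene signature `70G`, and two correlation scores `CSR`,
`CERBB`). The scientific background is documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

```python
import hypertabph as ht

# a synthetic 295-subject cohort generated at the published estimates
data = ht.generate_cohort(ht.CohortConfig(n=295, seed=7))   # 96 events

fit = ht.fit_ph(data)                 # hypertabastic PH, 4 covariates
print(fit.summary())
print(f"-2logL = {fit.minus_two_loglik:.4f}   AIC = {fit.aic:.4f}")
```

```
       estimate       se   wald    p_value  hazard_ratio
alpha   0.51773  0.28129 3.3877   0.065683           NaN
beta    0.61473  0.15758 15.219 9.5716e-05           NaN
AGE    -0.06256 0.022007 8.0809  0.0044735       0.93936
70G     0.93498  0.23108 16.372 5.2058e-05        2.5472
CSR       3.172  0.42434 55.877 7.7158e-14        23.855
CERBB    1.3914  0.39351 12.503 0.00040634        4.0205
-2logL = 804.1224   AIC = 816.1224
```

Each covariate row reads like a regression table: a one-unit rise in
CSR correlation multiplies the hazard ~24-fold (the score spans
[−1, 1], so realistic contrasts are fractions of that), while each year
of age at diagnosis lowers the hazard by ~6%. The fitted model is an
explicit function, so the dynamic quantities follow directly:

```python
profile = data.covariates.median().to_dict()      # reference patient
ht.conditional_survival(10, 20, profile, fit.spec)  # -> 0.7635
ht.peak_survival_decline(profile, fit.spec)
#   ExtremumResult(location=4.306, velocity=-0.0316, on_boundary=False)
ht.peak_hazard_rise(profile, fit.spec)
#   ExtremumResult(location=0.876, velocity=0.0139, on_boundary=False)
ht.compare_models(data)[["family", "aic"]]
#          family      aic
#   hypertabastic  816.122      <- generating family wins
#     loglogistic  817.324
#         weibull  817.855
```

A median-profile patient alive at 10 years has a 76% probability of
reaching 20; survival falls fastest around year 4.3 (−3.2 points/year),
and the hazard climbs fastest at ~0.9 years. The peak-hazard-rise *time*
is identical for every covariate profile — under proportional hazards
dh/dt = exp(x'θ)·h0′(t), so covariates scale the velocity but cannot
move its peak.

The same workflow is available from the shell:

```bash
hypertabph simulate --n 295 --seed 7 --out-dir out/
hypertabph fit out/cohort.csv --out-dir out/        # fit_report.json
hypertabph compare out/cohort.csv --out-dir out/    # model_comparison.csv
hypertabph dynamics out/cohort.csv --t1 10 --t2 20 --out-dir out/
```

`ParametricPH` is a scikit-learn estimator (`fit(X, y)` with y as a
structured event/time array, `get_params`/`set_params`, `predict*`
methods), so it composes with sklearn pipelines and model selection.

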