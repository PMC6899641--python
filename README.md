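# survref

Reference-based multiple imputation and information-anchored sensitivity
analysis for censored time-to-event data.

## The problem

The primary analysis of a time-to-event trial almost always assumes
*censoring at random* (CAR): conditional on model covariates, patients
censored at `c` have the same future event-time distribution as comparable
patients still in follow-up. When censoring marks an intercurrent event — a
switch to standard of care, a non-randomised intervention — that assumption
targets a *de jure* ("while on treatment") estimand, and regulators expect
sensitivity analyses under plausible *de facto* departures from it.

Reference-based imputation makes those departures concrete without asking
the analyst to invent numeric sensitivity parameters: a censored patient's
post-censoring hazard is set *by reference* to another arm's hazard. For a
patient on arm `x_i` with proportional-hazards rate
`h(t) = h0(t) exp(beta * x_i)` censored at `c_i`, the package supports

| rule  | post-censoring hazard for `t > c_i` |
|-------|-------------------------------------|
| CAR   | own-arm hazard (primary analysis) |
| J2R   | *jump to reference*: the reference arm's hazard |
| LHCF  | *last hazard carried forward*: own hazard frozen at `h_i(c_i)` |
| CIR   | *copy increments in reference*: reference-hazard shape rescaled to be continuous at `c_i` (equals CAR under proportional hazards) |
| delta | `Delta * h_act(t)` — a user-set multiplier, enabling tipping-point analysis |

Inference is by proper multiple imputation with a Weibull
proportional-hazards working model, `h(t) = kappa * t**(kappa-1) *
exp(alpha + beta' z)`: fit the model to the observed data, draw parameters
from `N(theta_hat, Sigma_hat)` on the `(alpha, log kappa, beta)` scale,
impute each censored time by inverting the conditional survivor
`S(t | t > c) = u` (closed form for every rule above), fit the substantive
model to each of K completed datasets, and combine with Rubin's rules
(`V = W + (1 + 1/K) B` with a t reference distribution).

The package also ships the Monte-Carlo harness showing *why* Rubin's rules
are the right variance here: reference-based rules borrow information from
the reference arm, so the naive empirical variance of the MI estimator
*shrinks* as censoring grows — implying, absurdly, that discarding data adds
information. Rubin's variance instead grows, approximately preserving the
*fraction* of information lost to censoring across the primary and
sensitivity analyses ("information anchoring").

## Worked example

Simulate a 250/arm exponential trial (control hazard 0.01/unit time, hazard
ratio 0.8) with ~40% of the active arm censored at random, then run the
primary fit, a Jump-to-Reference sensitivity analysis, and a delta
tipping-point sweep:

```console
$ survref simulate --n-per-arm 250 --censor-fraction 0.4 --seed 7 --out trial.csv
wrote 500 subjects to trial.csv

$ survref fit trial.csv
Weibull proportional-hazards fit
  events: 399
  loglik: -2275.661470
  alpha=-4.899879 log_kappa=+0.057126
  beta=[-0.253954]

$ survref impute trial.csv --method j2r --k 50 --seed 7 --out stacked.csv
wrote 50 imputations to stacked.csv

$ survref pool stacked.csv
estimate,se,hr,ci_low,ci_high,p_value,K,df
-0.157203,0.100642,0.854530,-0.354669,0.040262,0.118566,50,1126.75
```

Reading this: the observed-data fit estimates a log hazard ratio of −0.254
(treatment protective). Under the pessimistic J2R assumption — censored
active-arm patients revert to the control hazard — the pooled estimate
attenuates to −0.157 (HR 0.85, 95% CI 0.70–1.04 on the HR scale) and is no
longer significant: the trial's conclusion is sensitive to informative
censoring of this kind.

```console
$ survref tipping-point trial.csv --deltas 0.5,1,2,4,8 --k 20 --seed 7 --out tip.csv
conclusion changes at delta=2; wrote tip.csv
```

At `Delta = 1` the analysis reproduces CAR (significant, HR 0.77,
p = 0.013); doubling every censored patient's post-censoring hazard
(`Delta = 2`) is enough to lose significance — the tipping point.

The same pipeline is available as a library of scikit-learn-style
estimators:

```python
from survref import ReferenceBasedImputer, SurvivalData, pool

data = SurvivalData.from_csv("trial.csv")
imputer = ReferenceBasedImputer(method="J2R", K=50, random_state=7)
completed = imputer.fit_transform(data)   # 50 completed SurvivalData copies
```

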