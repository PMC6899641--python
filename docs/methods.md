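# Methods

## Substantive and imputation model

Both the primary analysis and the imputation model are the Weibull
proportional-hazards regression

    h(t | z) = kappa * t^(kappa-1) * exp(alpha + beta' z),
    H(t | z) = t^kappa * exp(alpha + beta' z),

with the binary treatment indicator as the first design column and any
baseline covariates after it. The censored-data log-likelihood
`sum_i [d_i log h(t_i) - H(t_i)]` is maximised on the unconstrained scale
`theta = (alpha, log kappa, beta)`; the log-shape parameterisation avoids
boundary failures and is also the scale on which proper-imputation
parameter draws `theta~ ~ N(theta_hat, Sigma_hat)` are taken, with
`Sigma_hat` the inverse observed information. Drawing on `kappa` directly
instead of `log kappa` would be an equally admissible "proper" choice; the
log scale was fixed once as the package's convention. Ties in event times
need no special handling under a parametric likelihood.

Optimisation is a damped Newton iteration with the analytic score and
Hessian, batched over datasets that share a design matrix — exactly the
shape of an MI analysis, where K completed copies differ only in their
time/event columns. Numerical safeguards: gradient-norm convergence
tolerance `1e-8 * n` with a 200-iteration cap; step-halving line search
(max 40 halvings); a capped score-direction step when the Hessian is
(near-)singular, which happens when all event times coincide and `alpha`
and `log kappa` become collinear; an L-BFGS-B fallback for stragglers; and
`|log kappa| >= 5` flagged as a boundary solution (a shape above ~150 only
arises from degenerate data) with a warning rather than an error, so
degenerate inputs terminate informatively.

Stratified fits (`stratify_by_arm=True`) are two fully independent per-arm
fits with arm-specific covariate coefficients and block-diagonal
covariance. They exist so that Jump-to-Reference and
copy-increments-in-reference can draw on arm-specific baseline hazards when
proportional hazards is in doubt; the default imputation model is the
single joint fit, whose reference-arm predictions come from setting the
treatment indicator to the reference arm.

## Post-censoring rules and imputation

For a subject censored at `c` with own-arm linear predictor `eta` and
reference predictor `eta_ref` (same covariates, arm switched), the
cumulative post-censoring hazard from `c` is

    CAR    exp(eta) * (t^k - c^k)
    J2R    exp(eta_ref) * (t^k_ref - c^k_ref)
    LHCF   k c^(k-1) exp(eta) * (t - c)
    CIR    [h_act(c)/h_ref(c)] * exp(eta_ref) * (t^k_ref - c^k_ref)
    DELTA  Delta * exp(eta) * (t^k - c^k)

Every rule is a shifted power law or linear function, so inverting the
conditional survivor `exp(-cum(t*)) = u` has a closed form; a numeric
bracketing oracle verifies the closed forms to 1e-10 relative tolerance in
the test suite. Uniforms are drawn on (0, 1] (u = 1 maps to `t* = c`
exactly; u = 0, an infinite time, is unreachable). Under a common-shape fit
CIR reduces to CAR identically; LHCF equals CAR when `kappa = 1`; J2R
equals CAR when the treatment effect is zero.

The J2R `switch_time_policy` option ("at_censoring" vs "at_origin") is
accepted for audit-trail purposes but produces the same conditional law:
given survival to `c`, only the hazard beyond `c` enters the conditional
survivor, and under J2R that is the reference hazard either way. For a
model with memory (e.g. frailty) the two policies would differ; not here.

Imputed subjects receive `event = 1` at `t*` unless a truncation horizon is
set (maximum follow-up), in which case times beyond it become censored
observations at the horizon — the usual convention when imputed times can
exceed the study period.

Random-stream discipline: one master seed; the study driver gives each
(replication, attempt) pair its own substream; within one `impute` call the
draw order is fixed (parameter vector first, then one uniform per censored
subject in dataset order, per imputation round). Runs are bitwise
reproducible for fixed inputs and seed. Per-subject substreams were
considered and rejected: they would preclude the vectorised imputation and
batched fitting that keep the full study inside a minute of CPU.

## Rubin's rules

Classical combination: `beta_bar = mean(b_k)`, `W = mean(v_k)`,
`B = var(b_k)` (divisor K−1), `V = W + (1 + 1/K) B`,
`df = (K-1)(1 + W/((1+1/K)B))^2` (infinite when B = 0, in which case the
interval collapses to the single-fit Wald interval). The Barnard–Rubin
small-sample df adjustment is available (`barnard_rubin=True` with the
complete-data df) but off by default, since the intended simulations have
large n. Pooling is on the log hazard ratio scale; HR-scale summaries are
exponentiated afterwards.

## Trial simulator and the censoring mechanism

Event times use the inverse-CDF construction
`T = (-log U / (h0 exp(beta x)))^(1/kappa)` with exactly `n_per_arm`
subjects per arm. Defaults are the primary study conditions: exponential
times (`kappa = 1`), control hazard `h0 = 0.01` per time unit, hazard ratio
0.8 (log HR −0.22314), 250 subjects per arm, K = 50 imputations, S = 1000
replications.

Censoring at random in the active arm is an *independent exponential*
censoring process: target fraction `f` gives censor rate
`theta = f * lambda / (1 - f)`, so `P(C < T) = f`; a subject is censored
iff `C < T`. Because `C` is independent of `T`, the mechanism is genuinely
noninformative and the censored-data MLE remains consistent — the defining
property of CAR, and the property the whole study relies on. Realised
censoring counts are Binomial(n, f) around the target. An exact-count
alternative (`mechanism="uniform_exact"`: a simple random sample of exactly
`round(f n)` subjects censored at `c ~ U(0, T)`) is provided for audits
that need the censoring percentage exact, with a documented caveat: tying
`c` to the subject's own `T` makes that scheme informative, and fitting
censored data generated by it gives materially biased estimates. It is not
used by the study driver. Note that for exponential event times
`E[min(T, C)] = (1 - f)/lambda` under *any* independent censoring law, so
mean-based summaries of the study do not depend on the censoring-time
distribution, but information-based quantities at heavy censoring do: with
exponential censoring at f = 0.8 the observed active-arm events concentrate
early, which couples the shape and treatment parameters and inflates the
observed-data variance relative to lighter-tailed censoring laws. The
exponential law was fixed as the default because it is the canonical
noninformative dropout model.

"Recreation" (the oracle benchmark) completes every censored record with
one draw from the assumption's post-censoring law at the *true* generating
parameters. Under CAR this reproduces the generating law exactly (verified
by fitting recreated data at large n); under J2R it defines the
assumption-implied estimand, estimated by fitting one very large recreated
trial (200000/arm by default; Monte-Carlo SE on the log HR about 0.003).

## Study driver

Per replication: generate, censor, (a) recreate under the assumption at the
truth, fit, record the estimate and inverse-information variance; (b) fit
the observed data, impute K times, fit each completed copy (one batched
Newton solve), pool. Per-scenario summaries are the means of (a)- and
(b)-quantities over S replications plus the empirical variances of both
estimators. A replication whose fit fails is redrawn on a fresh substream
(S stays fixed; the redraw count is reported and more than 1% of S aborts
the scenario). Replications are sequential but seeded independently, so
any future parallelisation cannot change results.

Information anchoring is summarised as the proportionate variance increase
(mean Rubin variance over mean recreated-data information variance) under
the primary CAR analysis and under the sensitivity rule; the anchored
variance is the sensitivity information variance inflated by the CAR ratio.
The 15% relative-agreement threshold applied for censoring up to 60% is an
operationalisation choice, configurable in `build_anchoring_report`.

The tipping-point sweep imputes under DELTA for each `Delta` on a grid,
pools, and reports the smallest `Delta` whose significance conclusion
differs from the one at `Delta` nearest 1. By the shared-uniform coupling,
imputed times are nonincreasing in `Delta`, so with the imputed arm being
the beneficial active arm the pooled log HR is monotone along the sweep up
to imputation noise.

## Problem sizes and runtime

The batched Newton core makes one scenario (S = 1000, K = 50, 250/arm)
about 13 s on one CPU; `scripts/acceptance.py` runs all five benchmark
scenarios plus the large implied-truth fit in about one minute. The test
suite uses S = 200 for its scenario benchmarks with Monte-Carlo tolerances
widened by the corresponding `sqrt(1000/S)` factor: three combined MC
standard errors for mean-type quantities, the chi-square-style
`3 v sqrt(2/(S-1) + 2/999)` band for variance-type quantities.

## What the synthetic data do and do not show

The generator emulates a clean two-arm trial: exponential event times,
perfectly balanced arms, censoring confined to the active arm, no
covariates, no administrative censoring, no staggered accrual. Passing
benchmarks therefore demonstrate the statistical machinery (likelihood,
inversion, pooling, anchoring diagnostics) under the stated conditions —
not robustness to covariate-dependent censoring, non-proportional hazards,
or misspecified baseline hazards. Covariate-adjusted imputation is
supported (the subject's own covariates enter both `eta` and `eta_ref`;
only the arm indicator is switched) but the simulation study does not
exercise it.

## Known limitations

- Proportional hazards is assumed in both the analysis and imputation
  models; all reference-based rules except CAR strictly violate it in the
  completed data, so the pooled estimate is an average hazard ratio.
  Flexible (spline) baseline hazards and restricted-mean summaries are out
  of scope.
- Single event type; no competing risks, left truncation, interval
  censoring, or time-varying covariates.
- One assumption per run: mixtures of rules by censoring reason must be
  composed by the caller on subject subsets.
- The Weibull MLE carries O(1/n) small-sample bias (visible at 250/arm as a
  few thousandths on the log HR); no bias correction is applied, matching
  standard practice.
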