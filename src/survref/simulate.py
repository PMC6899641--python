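"""Two-arm trial simulator with known truth, CAR censoring, and oracle
"recreation" of censored observations under a stated assumption.

The generating process is Weibull (exponential by default): subject i in arm
x has cumulative hazard H(t) = h0 * exp(beta * x) * t**kappa, and event times
come from the inverse-CDF construction T = (-log U / (h0 exp(beta x)))**(1/kappa)
with U ~ U(0,1) — the standard survival-simulation recipe.

Censoring at random in the active arm is applied by an *independent*
exponential censoring process: with target fraction f and arm event rate
lam, censoring times C ~ Exp(theta) with theta = f*lam/(1-f) give
P(C < T) = theta/(theta+lam) = f. Because C is independent of T the
mechanism is genuinely noninformative, so the censored-data MLE stays
consistent; realised censoring counts are Binomial(n, f) around the target.
An exact-count scheme ("uniform_exact": a simple random sample of exactly
round(f*n) subjects censored at U(0, T)) is available for audits that need
the censoring percentage to be exact, but note that drawing c from U(0, T)
ties the censoring time to the event time and the scheme is therefore mildly
informative; it is not used by the study driver.

"Recreation" completes every censored observation with a single draw from
the post-censoring law of a given assumption evaluated at the *true*
generating parameters — the oracle benchmark the multiple-imputation
estimator is judged against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assumptions import Assumption, hazard_constants
from .datasets import SurvivalData
from .exceptions import SpecificationError
from .impute import _uniforms_open_closed


@dataclass(frozen=True)
class TrueParams:
    """Generating parameters on the PH scale: H(t) = t**kappa * exp(alpha + beta x)."""

    alpha: float   # log rate-scale of the reference arm (log h0 when kappa=1)
    kappa: float
    beta: float    # log hazard ratio of the active arm

    @classmethod
    def from_scenario(cls, control_hazard: float, hazard_ratio: float,
                      shape: float) -> "TrueParams":
        return cls(alpha=float(np.log(control_hazard)), kappa=float(shape),
                   beta=float(np.log(hazard_ratio)))


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation factorial.

    Defaults are the primary study conditions: exponential event times with
    control-arm hazard 0.01 per time unit, hazard ratio 0.8, 250 subjects
    per arm, K=50 imputations, S=1000 replications.
    """

    n_per_arm: int = 250
    control_hazard: float = 0.01
    hazard_ratio: float = 0.8
    censor_fraction: float = 0.0
    shape: float = 1.0
    K: int = 50
    S: int = 1000
    master_seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 2:
            raise SpecificationError("n_per_arm must be >= 2")
        if not (self.control_hazard > 0 and self.hazard_ratio > 0 and self.shape > 0):
            raise SpecificationError("hazards, ratio and shape must be positive")
        if not (0.0 <= self.censor_fraction < 1.0):
            raise SpecificationError("censor_fraction must lie in [0, 1)")

    @property
    def truth(self) -> TrueParams:
        return TrueParams.from_scenario(self.control_hazard, self.hazard_ratio,
                                        self.shape)


def event_times_from_uniforms(u, rate, kappa: float = 1.0) -> np.ndarray:
    """Inverse-CDF event times T = (-log u / rate)**(1/kappa)."""
    u = np.asarray(u, float)
    return (-np.log(u) / np.asarray(rate, float)) ** (1.0 / kappa)


def generate_trial(config: ScenarioConfig, rng=None) -> SurvivalData:
    """Fully observed two-arm trial: exactly n_per_arm per arm, all events."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = config.n_per_arm
    arm = np.repeat([0, 1], n)
    rate = config.control_hazard * config.hazard_ratio ** arm
    u = 1.0 - rng.random(2 * n)  # (0, 1]: avoids log(0)
    t = event_times_from_uniforms(u, rate, config.shape)
    frame = pd.DataFrame({
        "subject_id": [f"s{i:06d}" for i in range(2 * n)],
        "time": t, "event": 1, "arm": arm,
    })
    return SurvivalData.from_frame(frame)


def apply_car_censoring(data: SurvivalData, fraction: float, arm: int = 1,
                        rng=None, mechanism: str = "exponential",
                        event_rate: float | None = None) -> SurvivalData:
    """Censor subjects of one arm at random at a target fraction.

    mechanism="exponential" (default): independent censoring times
    C ~ Exp(theta), theta = fraction*rate/(1-fraction); a subject is censored
    iff C < T. ``event_rate`` supplies the arm's event rate; if omitted it is
    estimated from the arm's data by the exponential method of moments
    (events / total time).

    mechanism="uniform_exact": a simple random sample of exactly
    round(fraction * n_arm) subjects is censored, each at c ~ U(0, T).
    """
    if not (0.0 <= fraction < 1.0):
        raise SpecificationError("fraction must lie in [0, 1)")
    if fraction == 0.0:
        return data
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    times = data.times.copy()
    events = data.events.copy()
    in_arm = np.flatnonzero(data.arms == arm)
    if in_arm.size == 0:
        raise SpecificationError(f"arm {arm} absent from the data")
    t_arm = times[in_arm]

    if mechanism == "exponential":
        rate = event_rate if event_rate is not None else \
            float(events[in_arm].sum() / t_arm.sum())
        theta = fraction * rate / (1.0 - fraction)
        c = rng.exponential(1.0 / theta, size=in_arm.size)
        sel = c < t_arm
        times[in_arm[sel]] = c[sel]
        events[in_arm[sel]] = 0
    elif mechanism == "uniform_exact":
        m = int(round(fraction * in_arm.size))
        chosen = rng.choice(in_arm, size=m, replace=False)
        c = rng.random(m) * times[chosen]
        times[chosen] = c
        events[chosen] = 0
    else:
        raise SpecificationError(f"unknown censoring mechanism {mechanism!r}")
    return data.with_rows(times, events)


def recreate_under_assumption(censored: SurvivalData, truth: TrueParams,
                              assumption: Assumption, rng=None) -> SurvivalData:
    """Complete every censored record from the assumption at the TRUE parameters.

    Oracle benchmark: each censored subject gets a single draw from the
    assumption's post-censoring law evaluated at the generating (alpha,
    kappa, beta) — not at a fitted model. Under CAR this reproduces the
    original generating process.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    cens = censored.events == 0
    if not cens.any():
        return censored
    c = censored.times[cens]
    x = censored.arms[cens].astype(float)
    eta = truth.alpha + truth.beta * x
    eta_ref = truth.alpha + truth.beta * float(assumption.reference_arm) \
        * np.ones_like(x)
    kap = np.full_like(x, truth.kappa)
    coef, shape, form = hazard_constants(
        assumption.method, eta, kap, eta_ref, kap, assumption.delta, c)
    u = _uniforms_open_closed(rng, c.size)
    m = -np.log(u)
    tstar = c + m / coef if form == "linear" else \
        (c ** shape + m / coef) ** (1.0 / shape)
    times = censored.times.copy()
    events = censored.events.copy()
    times[cens] = tstar
    events[cens] = 1
    return censored.with_rows(times, events)
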