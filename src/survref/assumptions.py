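"""Post-censoring hazard assumptions for reference-based imputation.

For a subject censored at c, the analysis keeps the fitted hazard up to c and
replaces it beyond c with an assumption-specific hazard h_post. Writing
eta = alpha + beta'z for the subject's own-arm linear predictor and eta_ref
for the same subject with the arm indicator switched to the reference arm,
the cumulative post-censoring hazard integral(c..t) h_post(u) du is

    CAR    exp(eta) * (t**k - c**k)                    censoring at random
    J2R    exp(eta_ref) * (t**k_ref - c**k_ref)        jump to reference
    LHCF   k * c**(k-1) * exp(eta) * (t - c)           last hazard carried fwd
    CIR    [h_act(c)/h_ref(c)] * exp(eta_ref) * (t**k_ref - c**k_ref)
    DELTA  delta * exp(eta) * (t**k - c**k)            delta sensitivity

where k / k_ref are the (own / reference) Weibull shapes — identical under a
common, unstratified fit, in which case CIR reduces exactly to CAR.

Imputed event times come from inverting the conditional survivor function:
with u ~ U(0, 1], solve exp(-cum(t*)) = u, i.e. cum(t*) = -log u. Every rule
above is either a shifted power law A*(t**k - c**k) or linear A*(t - c), so
the inversion has a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .exceptions import SpecificationError

Method = Literal["CAR", "J2R", "LHCF", "CIR", "DELTA"]
METHODS: tuple[str, ...] = ("CAR", "J2R", "LHCF", "CIR", "DELTA")


@dataclass(frozen=True)
class Assumption:
    """A tagged post-censoring hazard rule.

    Parameters
    ----------
    method : {"CAR", "J2R", "LHCF", "CIR", "DELTA"}
    delta : float, optional
        Hazard multiplier, required iff ``method == "DELTA"``; delta > 1
        worsens the post-censoring prognosis of imputed subjects.
    reference_arm : int, default 0
        Arm whose hazard plays the reference role for J2R/CIR.
    switch_time_policy : {"at_censoring", "at_origin"}, default "at_censoring"
        J2R only. For hazard-based rules the two policies induce the same
        conditional law given survival to c (only the post-c hazard enters
        the conditional survivor), so this is a labelling choice; it is
        validated and recorded for the audit trail.
    """

    method: str
    delta: float | None = None
    reference_arm: int = 0
    switch_time_policy: str = "at_censoring"

    def __post_init__(self):
        m = self.method.upper()
        if m not in METHODS:
            raise SpecificationError(f"unknown method {self.method!r}; "
                                     f"expected one of {METHODS}")
        object.__setattr__(self, "method", m)
        if m == "DELTA":
            if self.delta is None:
                raise SpecificationError("method DELTA requires a delta multiplier")
            if not (self.delta > 0):
                raise SpecificationError("delta must be > 0")
        elif self.delta is not None:
            raise SpecificationError(f"delta is only meaningful for DELTA, not {m}")
        if self.reference_arm not in (0, 1):
            raise SpecificationError("reference_arm must be 0 or 1")
        if self.switch_time_policy not in ("at_censoring", "at_origin"):
            raise SpecificationError("switch_time_policy must be 'at_censoring' "
                                     "or 'at_origin'")
        if self.switch_time_policy == "at_origin" and m != "J2R":
            raise SpecificationError("switch_time_policy='at_origin' is only "
                                     "permitted for J2R")

    @property
    def label(self) -> str:
        if self.method == "DELTA":
            return f"DELTA(delta={self.delta:g})"
        return self.method


def car() -> Assumption:
    return Assumption("CAR")


def jump_to_reference(reference_arm: int = 0) -> Assumption:
    return Assumption("J2R", reference_arm=reference_arm)


def delta_adjusted(delta: float) -> Assumption:
    return Assumption("DELTA", delta=delta)


# ----------------------------------------------------------------- hazards
class PostCensoringHazard:
    """Cumulative post-censoring hazard of one censored subject.

    Either a power form A*(t**k - c**k) or a linear form A*(t - c); both are
    zero at c, nondecreasing and unbounded, so the conditional-survivor
    inversion always terminates.
    """

    __slots__ = ("censor_time", "coef", "shape", "form", "description")

    def __init__(self, censor_time: float, coef: float, shape: float,
                 form: str, description: str):
        if not censor_time > 0:
            raise SpecificationError("censoring time must be positive")
        if not (coef > 0 and np.isfinite(coef)):
            raise SpecificationError("hazard coefficient must be positive finite")
        self.censor_time = float(censor_time)
        self.coef = float(coef)
        self.shape = float(shape)
        self.form = form
        self.description = description

    def cumulative(self, t):
        """integral(c..t) h_post(u) du for t >= c (vectorised)."""
        t = np.asarray(t, float)
        c = self.censor_time
        if np.any(t < c - 1e-12):
            raise ValueError("cumulative hazard requested before the censoring time")
        if self.form == "linear":
            out = self.coef * (t - c)
        else:
            out = self.coef * (t ** self.shape - c ** self.shape)
        return np.maximum(out, 0.0)

    def invert(self, u):
        """Imputed time t* >= c with exp(-cumulative(t*)) = u, u in (0, 1]."""
        u = np.asarray(u, float)
        if np.any(u <= 0) or np.any(u > 1):
            raise ValueError("u must lie in (0, 1]; u=0 maps to an infinite time")
        m = -np.log(u)
        c = self.censor_time
        if self.form == "linear":
            return c + m / self.coef
        # clamp guards roundoff in (c**k)**(1/k) at u ~ 1
        return np.maximum((c ** self.shape + m / self.coef) ** (1.0 / self.shape), c)


def hazard_constants(method: str, eta, kappa, eta_ref, kappa_ref, delta, c):
    """(coef, shape, form) of the cumulative post-censoring hazard.

    Vectorised over subjects: every argument may be an array. This is the
    closed-form core shared by :func:`build_post_hazard` and the batched
    imputation path.
    """
    eta = np.asarray(eta, float)
    kappa = np.asarray(kappa, float)
    c = np.asarray(c, float)
    if method == "CAR":
        return np.exp(eta), kappa, "power"
    if method == "DELTA":
        return delta * np.exp(eta), kappa, "power"
    if method == "LHCF":
        # h(c) frozen: kappa * c**(kappa-1) * exp(eta)
        return kappa * c ** (kappa - 1.0) * np.exp(eta), None, "linear"
    eta_ref = np.asarray(eta_ref, float)
    kappa_ref = np.asarray(kappa_ref, float)
    if method == "J2R":
        return np.exp(eta_ref), kappa_ref, "power"
    if method == "CIR":
        h_act = kappa * c ** (kappa - 1.0) * np.exp(eta)
        h_ref = kappa_ref * c ** (kappa_ref - 1.0) * np.exp(eta_ref)
        return (h_act / h_ref) * np.exp(eta_ref), kappa_ref, "power"
    raise SpecificationError(f"unknown method {method!r}")


def build_post_hazard(assumption: Assumption, theta, fit, c: float,
                      arm: int, covariates=None) -> PostCensoringHazard:
    """Post-censoring hazard for one subject under ``assumption``.

    Parameters
    ----------
    assumption : Assumption
    theta : parameter draw in the layout of ``fit`` (vector, or per-arm dict
        for stratified fits), typically from ``fit.draw_parameters``
    fit : WeibullPH
        Supplies the parameter layout (which entries are alpha / log kappa /
        betas, stratified or not); its fitted values are *not* used when a
        draw is supplied.
    c : float
        Censoring time (> 0).
    arm : int
        The subject's own arm.
    covariates : 1-d array, optional
        The subject's own baseline covariates; carried unchanged into both
        the own-arm and reference-arm linear predictors (only the arm
        indicator is switched for J2R/CIR).
    """
    if not c > 0:
        raise SpecificationError("censoring time must be positive")
    method = assumption.method
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    needs_ref = method in ("J2R", "CIR")
    if fit.stratify_by_arm and needs_ref and not isinstance(theta, dict):
        raise SpecificationError("stratified fit requires per-arm parameters "
                                 "for J2R/CIR")
    eta, kappa = fit._eta_kappa(np.array([arm]), cov, theta=theta)
    eta_ref = kappa_ref = None
    if needs_ref:
        eta_ref, kappa_ref = fit._eta_kappa(
            np.array([assumption.reference_arm]), cov, theta=theta)
        eta_ref, kappa_ref = float(eta_ref[0]), float(kappa_ref[0])
    coef, shape, form = hazard_constants(
        method, float(eta[0]), float(kappa[0]), eta_ref, kappa_ref,
        assumption.delta, c)
    desc = (f"{assumption.label} post-censoring hazard, c={c:g}, arm={arm}, "
            f"reference_arm={assumption.reference_arm}")
    return PostCensoringHazard(c, float(coef), 1.0 if shape is None else float(shape),
                               form, desc)


def invert_conditional_survivor(ph: PostCensoringHazard, u) -> float | np.ndarray:
    """Solve S(t | t > c) = u for the imputed time (closed form)."""
    out = ph.invert(u)
    return float(out) if np.ndim(u) == 0 else out
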