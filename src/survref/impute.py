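"""Multiple imputation of censored event times under a post-censoring rule.

Proper-imputation algorithm, per imputation round k = 1..K:

1. draw model parameters theta_k ~ N(theta_hat, vcov) on the
   (alpha, log kappa, beta) scale;
2. for every censored subject, draw u ~ U(0, 1] and invert the conditional
   survivor implied by the assumption's post-censoring hazard at theta_k,
   giving an imputed event time t* > c;
3. record (t*, event=1), unless a truncation horizon is set and t* exceeds
   it, in which case the subject is censored at the horizon (the usual
   maximum-follow-up convention).

Observed events pass through untouched and are bit-identical across the K
completed copies. Draw order within a round is fixed (parameter vector first,
then one uniform per censored subject in dataset order), so results are
bitwise reproducible for a given seed and input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .assumptions import Assumption, hazard_constants
from .datasets import SurvivalData
from .exceptions import SpecificationError
from .weibull import WeibullPH, fit_weibull_ph


@dataclass
class ImputationSet:
    """K completed copies of a dataset plus the provenance of the run."""

    completed: list[SurvivalData]
    K: int
    assumption: Assumption
    seed_state: str
    truncation_time: float | None = None

    def __iter__(self):
        return iter(self.completed)

    def __len__(self):
        return len(self.completed)


def _uniforms_open_closed(rng: np.random.Generator, size: int) -> np.ndarray:
    """U(0, 1]: 1 - random() maps [0,1) to (0,1], so u=0 never occurs."""
    return 1.0 - rng.random(size)


def _round_times(data: SurvivalData, fit: WeibullPH, assumption: Assumption,
                 theta, u: np.ndarray, cens: np.ndarray) -> np.ndarray:
    """Imputed times for the censored subjects (vectorised over subjects)."""
    c = data.times[cens]
    arms = data.arms[cens]
    cov = data.covariates()[cens]
    eta, kappa = fit._eta_kappa(arms, cov, theta=theta)
    eta_ref = kappa_ref = None
    if assumption.method in ("J2R", "CIR"):
        ref = np.full_like(arms, assumption.reference_arm)
        eta_ref, kappa_ref = fit._eta_kappa(ref, cov, theta=theta)
    coef, shape, form = hazard_constants(
        assumption.method, eta, kappa, eta_ref, kappa_ref, assumption.delta, c)
    m = -np.log(u)
    if form == "linear":
        return c + m / coef
    return (c ** shape + m / coef) ** (1.0 / shape)


def impute_times(data: SurvivalData, fit: WeibullPH, assumption: Assumption,
                 K: int, rng: np.random.Generator,
                 truncation_time: float | None = None):
    """Array core: (times (K, n), events (K, n)) of the completed copies."""
    if K < 2:
        raise SpecificationError("K must be at least 2 for multiple imputation")
    if truncation_time is not None and not truncation_time > 0:
        raise SpecificationError("truncation_time must be positive")
    if data.covariate_names and data.covariates().shape[1] != \
            getattr(fit, "n_features_in_", 1) - 1:
        raise SpecificationError(
            "covariate schema of the dataset does not match the fitted model")
    cens = data.events == 0
    n = data.n
    T = np.tile(data.times, (K, 1))
    D = np.tile(data.events.astype(float), (K, 1))
    if not cens.any():
        return T, D
    m = int(cens.sum())
    for k in range(K):
        theta = fit.draw_parameters(rng)
        u = _uniforms_open_closed(rng, m)
        tstar = _round_times(data, fit, assumption, theta, u, cens)
        ev = np.ones(m)
        if truncation_time is not None:
            over = tstar > truncation_time
            tstar = np.where(over, truncation_time, tstar)
            ev = np.where(over, 0.0, 1.0)
        T[k, cens] = tstar
        D[k, cens] = ev
    return T, D


def impute_dataset(data: SurvivalData, fit: WeibullPH, assumption: Assumption,
                   K: int, random_state=None,
                   truncation_time: float | None = None) -> ImputationSet:
    """Produce K completed :class:`SurvivalData` copies of ``data``.

    ``fit`` must have been produced from ``data`` (or a superset with the
    same covariate schema). Subjects with observed events are identical
    across copies; every imputed time strictly exceeds that subject's
    censoring time (before any truncation).
    """
    rng = random_state if isinstance(random_state, np.random.Generator) \
        else np.random.default_rng(random_state)
    state = repr(rng.bit_generator.state.get("state", {}))
    T, D = impute_times(data, fit, assumption, K, rng, truncation_time)
    completed = [data.with_rows(T[k], D[k]) for k in range(K)]
    return ImputationSet(completed, K, assumption, state, truncation_time)


class ReferenceBasedImputer(BaseEstimator):
    """Reference-based multiple imputer for censored survival data.

    scikit-learn-style transformer over :class:`SurvivalData`: ``fit``
    estimates the Weibull PH imputation model on the observed data,
    ``transform`` produces an :class:`ImputationSet` of K completed copies
    under the configured post-censoring assumption.

    Parameters
    ----------
    method : {"CAR", "J2R", "LHCF", "CIR", "DELTA"}, default "CAR"
    delta : float, optional — multiplier for the DELTA method.
    reference_arm : int, default 0
    K : int, default 50 — number of imputations.
    truncation_time : float, optional — maximum follow-up; imputed times
        beyond it become censored observations at the horizon.
    stratify_by_arm : bool, default False — arm-specific baseline hazards in
        the imputation model.
    random_state : int or numpy Generator, optional.
    """

    def __init__(self, method: str = "CAR", delta: float | None = None,
                 reference_arm: int = 0, K: int = 50,
                 truncation_time: float | None = None,
                 stratify_by_arm: bool = False, random_state=None):
        self.method = method
        self.delta = delta
        self.reference_arm = reference_arm
        self.K = K
        self.truncation_time = truncation_time
        self.stratify_by_arm = stratify_by_arm
        self.random_state = random_state

    @property
    def assumption_(self) -> Assumption:
        return Assumption(self.method, delta=self.delta,
                          reference_arm=self.reference_arm)

    def fit(self, data: SurvivalData, y=None):
        self.model_ = fit_weibull_ph(data, stratify_by_arm=self.stratify_by_arm)
        return self

    def transform(self, data: SurvivalData) -> ImputationSet:
        if not hasattr(self, "model_"):
            raise SpecificationError("imputer is not fitted; call fit first")
        return impute_dataset(data, self.model_, self.assumption_, self.K,
                              random_state=self.random_state,
                              truncation_time=self.truncation_time)

    def fit_transform(self, data: SurvivalData, y=None) -> ImputationSet:
        return self.fit(data).transform(data)
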