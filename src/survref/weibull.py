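"""Weibull proportional-hazards regression by maximum likelihood.

Model: for subject i with design row z_i (treatment indicator first, then
baseline covariates), the hazard and cumulative hazard are

    h(t) = kappa * t**(kappa-1) * exp(alpha + beta' z_i)
    H(t) = t**kappa * exp(alpha + beta' z_i)

and the censored-data log-likelihood is sum_i [ d_i*log h(t_i) - H(t_i) ].
The model is parameterised on theta = (alpha, log kappa, beta): the log-shape
scale keeps the optimisation unconstrained, and posterior parameter draws for
proper multiple imputation are taken on this same scale.

Fitting is a damped Newton iteration with the analytic score and Hessian,
*batched* over many datasets that share one design matrix — exactly the shape
of a multiple-imputation analysis, where K completed copies of a trial differ
only in their time/event columns. The observed-information inverse provides
the covariance matrix.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .datasets import SurvivalData
from .exceptions import ConvergenceError, DegenerateDataError, MatrixError

_LK_BOUND = 30.0    # hard clip for the optimiser
_LK_SUSPECT = 5.0   # |log kappa| beyond this flags a boundary solution
                    # (kappa > ~150 only arises from degenerate data)


# --------------------------------------------------------------------- core
def censored_weibull_loglik(theta: np.ndarray, t: np.ndarray, d: np.ndarray,
                            Z: np.ndarray) -> float:
    """Log-likelihood at theta=(alpha, log kappa, beta) for one dataset."""
    theta = np.asarray(theta, float)
    alpha, lk = theta[0], theta[1]
    beta = theta[2:]
    kappa = np.exp(lk)
    logt = np.log(t)
    eta = alpha + Z @ beta
    w = np.exp(eta + kappa * logt)  # H(t_i)
    return float(np.sum(d * (lk + (kappa - 1.0) * logt + eta) - w))


def _ll_grad_hess(theta, T, D, Z, logT):
    """Batched value/score/Hessian. theta (K,q); T,D,logT (K,n); Z (n,p)."""
    alpha = theta[:, 0]
    lk = theta[:, 1]
    beta = theta[:, 2:]
    kappa = np.exp(lk)
    with np.errstate(over="ignore", invalid="ignore"):
        eta = alpha[:, None] + beta @ Z.T                  # (K,n)
        s = kappa[:, None] * logT                          # kappa*log t
        w = np.exp(eta + s)                                # H(t_i)
        r = D - w
        ll = np.sum(D * (lk[:, None] + s - logT + eta) - w, axis=1)

    K, n = T.shape
    p = Z.shape[1]
    q = 2 + p
    g = np.empty((K, q))
    H = np.empty((K, q, q))
    with np.errstate(over="ignore", invalid="ignore"):
        g[:, 0] = r.sum(axis=1)
        g[:, 1] = (D + r * s).sum(axis=1)
        g[:, 2:] = r @ Z
        ws = w * s
        H[:, 0, 0] = -w.sum(axis=1)
        H[:, 0, 1] = H[:, 1, 0] = -ws.sum(axis=1)
        H[:, 1, 1] = (r * s).sum(axis=1) - (ws * s).sum(axis=1)
        if p:
            wZ = w @ Z
            wsZ = ws @ Z
            H[:, 0, 2:] = H[:, 2:, 0] = -wZ
            H[:, 1, 2:] = H[:, 2:, 1] = -wsZ
            H[:, 2:, 2:] = -np.einsum("kn,nj,nl->kjl", w, Z, Z)
    return ll, g, H


def _newton_fit(T: np.ndarray, D: np.ndarray, Z: np.ndarray,
                gtol_scale: float = 1e-8, max_iter: int = 200):
    """Damped Newton MLE, batched over the leading axis of T/D.

    Returns (theta (K,q), loglik (K,), converged (K,), boundary (K,)).
    """
    T = np.atleast_2d(np.asarray(T, float))
    D = np.atleast_2d(np.asarray(D, float))
    K, n = T.shape
    p = Z.shape[1]
    q = 2 + p
    logT = np.log(T)
    gtol = gtol_scale * max(n, 1.0)

    theta = np.zeros((K, q))
    # alpha init: log crude event rate; log kappa = 0; beta = 0
    theta[:, 0] = np.log(np.maximum(D.sum(axis=1), 0.5) / T.sum(axis=1))

    ll, g, H = _ll_grad_hess(theta, T, D, Z, logT)
    active = np.ones(K, bool)
    for _ in range(max_iter):
        conv = np.max(np.abs(g), axis=1) <= gtol
        active = ~conv & (np.abs(theta[:, 1]) < _LK_BOUND)
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Ha = H[idx]
        # ridge the Hessian if singular / not negative definite enough
        try:
            step = np.linalg.solve(Ha, -g[idx][..., None])[..., 0]
        except np.linalg.LinAlgError:
            Ha = Ha - 1e-8 * np.eye(q) * (1.0 + np.abs(Ha).max())
            step = np.linalg.solve(Ha, -g[idx][..., None])[..., 0]
        # (near-)singular Hessians (e.g. identical event times make alpha and
        # log kappa collinear) give garbage steps: fall back to a capped
        # ascent step along the score
        norm = np.max(np.abs(step), axis=1)
        wild = ~np.isfinite(norm) | (norm > 50.0)
        if wild.any():
            gw = g[idx][wild]
            step[wild] = gw / (np.max(np.abs(gw), axis=1, keepdims=True) + 1e-12)
        # line search by step halving on the log-likelihood
        scale = np.ones(len(idx))
        for _half in range(40):
            cand = theta[idx] + scale[:, None] * step
            cand[:, 1] = np.clip(cand[:, 1], -_LK_BOUND, _LK_BOUND)
            ll_c, g_c, H_c = _ll_grad_hess(cand, T[idx], D[idx], Z, logT[idx])
            bad = ~np.isfinite(ll_c) | (ll_c < ll[idx] - 1e-12 * (1 + np.abs(ll[idx])))
            if not bad.any():
                break
            scale[bad] *= 0.5
        theta[idx] = cand
        ll[idx], g[idx], H[idx] = ll_c, g_c, H_c

    converged = np.max(np.abs(g), axis=1) <= gtol
    boundary = np.abs(theta[:, 1]) >= _LK_SUSPECT

    # fall back to a quasi-Newton line-search method for stragglers
    for k in np.flatnonzero(~converged & ~boundary):
        res = optimize.minimize(
            lambda th: -censored_weibull_loglik(th, T[k], D[k], Z),
            theta[k], method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-14, "gtol": gtol / 10},
        )
        thk = np.asarray(res.x, float)
        llk, gk, Hk = _ll_grad_hess(thk[None], T[k:k + 1], D[k:k + 1], Z,
                                    logT[k:k + 1])
        if np.max(np.abs(gk)) <= 10 * gtol:
            theta[k], ll[k], g[k], H[k] = thk, llk[0], gk[0], Hk[0]
            converged[k] = True
    return theta, ll, converged, boundary, H


def _vcov_from_hessian(H: np.ndarray) -> np.ndarray:
    """Inverse observed information: inv(-H), batched, symmetrised."""
    V = np.linalg.inv(-H)
    return 0.5 * (V + np.swapaxes(V, -1, -2))


def fit_many(T: np.ndarray, D: np.ndarray, Z: np.ndarray):
    """Fit the model to K datasets sharing the design Z.

    Returns (theta (K,q), vcov (K,q,q), loglik (K,)). Raises
    :class:`ConvergenceError` if any batch member fails.
    """
    theta, ll, converged, boundary, H = _newton_fit(T, D, Z)
    if not (converged | boundary).all():
        raise ConvergenceError(
            f"{int((~converged).sum())} of {len(theta)} fits failed to converge"
        )
    return theta, _vcov_from_hessian(H), ll


# ---------------------------------------------------------------- estimator
class WeibullPH(BaseEstimator):
    """Weibull proportional-hazards model, scikit-learn style.

    Parameters
    ----------
    stratify_by_arm : bool, default False
        If True, fit separate (alpha, log kappa, covariate betas) per arm
        (no treatment coefficient); used so that reference-based rules can
        draw on arm-specific baseline hazards under non-proportionality.

    Call ``fit(X, y)`` with ``X`` of shape (n, 1+p) whose **first column is
    the binary treatment indicator** and remaining columns are covariates,
    and ``y`` either a (n, 2) array ``[time, event]`` or a structured array
    with ``time``/``event`` fields (scikit-survival convention).

    Attributes (unstratified)
    -------------------------
    alpha_, log_kappa_, kappa_ : floats
    beta_ : ndarray (1+p,), treatment coefficient first
    vcov_ : ndarray (q, q) over (alpha, log kappa, beta) — inverse observed
        information at the MLE
    loglik_, n_events_, converged_, boundary_ : fit diagnostics

    Attributes (stratified)
    -----------------------
    alpha_by_arm_, log_kappa_by_arm_ : ndarray (2,), index = arm label
    beta_by_arm_ : ndarray (2, p)
    vcov_by_arm_ : list of two (2+p, 2+p) matrices
    """

    def __init__(self, stratify_by_arm: bool = False):
        self.stratify_by_arm = stratify_by_arm

    # ------------------------------------------------------------ utilities
    @staticmethod
    def _split_y(y) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(y, tuple) and len(y) == 2:
            t, d = y
        elif hasattr(y, "dtype") and y.dtype.names:
            names = y.dtype.names
            tname = "time" if "time" in names else names[1]
            dname = "event" if "event" in names else names[0]
            t, d = y[tname], y[dname]
        else:
            arr = np.asarray(y, float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("y must be (time, event), a structured array, "
                                 "or an (n, 2) array [time, event]")
            t, d = arr[:, 0], arr[:, 1]
        t = np.asarray(t, float)
        d = np.asarray(d, float)
        if (t <= 0).any():
            raise ValueError("times must be positive")
        if not np.isin(d, (0.0, 1.0)).all():
            raise ValueError("event indicator must be 0/1")
        return t, d

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (first column = treatment indicator)")
        t, d = self._split_y(y)
        arm = X[:, 0]
        if not np.isin(arm, (0.0, 1.0)).all():
            raise ValueError("first column of X must be a 0/1 treatment indicator")
        self.n_features_in_ = X.shape[1]
        self.n_events_ = int(d.sum())

        if self.stratify_by_arm:
            self._fit_stratified(X, t, d)
            return self

        for a in np.unique(arm):
            if d[arm == a].sum() < 1:
                raise DegenerateDataError(f"arm {int(a)} has no observed events")
        if d.sum() < 2:
            raise DegenerateDataError("need at least 2 events overall")

        # single-arm data: the treatment column is collinear with the
        # intercept; drop it and flag
        self.single_arm_ = len(np.unique(arm)) == 1
        Z = X[:, 1:] if self.single_arm_ else X

        theta, ll, converged, boundary, H = _newton_fit(t[None], d[None], Z)
        theta, ll, H = theta[0], ll[0], H[0]
        self.converged_ = bool(converged[0])
        self.boundary_ = bool(boundary[0])
        if self.boundary_:
            warnings.warn(
                "Weibull shape at optimisation boundary (log kappa = "
                f"{theta[1]:+.1f}); estimates are a boundary solution",
                RuntimeWarning,
            )
        elif not self.converged_:
            raise ConvergenceError("Weibull PH fit did not converge",
                                   context=f"n={len(t)}, events={self.n_events_}")
        self.alpha_ = float(theta[0])
        self.log_kappa_ = float(theta[1])
        self.kappa_ = float(np.exp(theta[1]))
        self.beta_ = theta[2:].copy()
        self.theta_ = theta.copy()
        self.loglik_ = float(ll)
        try:
            self.vcov_ = _vcov_from_hessian(H[None])[0]
        except np.linalg.LinAlgError:
            self.vcov_ = np.full((len(theta), len(theta)), np.nan)
        return self

    def _fit_stratified(self, X, t, d):
        arm = X[:, 0]
        self.single_arm_ = False
        alphas = np.full(2, np.nan)
        lks = np.full(2, np.nan)
        p = X.shape[1] - 1
        betas = np.full((2, p), np.nan)
        self.vcov_by_arm_ = [None, None]
        self.loglik_ = 0.0
        self.converged_ = True
        self.boundary_ = False
        for a in (0, 1):
            m = arm == a
            if not m.any():
                raise DegenerateDataError(f"arm {a} absent from the data")
            if d[m].sum() < 1:
                raise DegenerateDataError(f"arm {a} has no observed events")
            theta, ll, converged, boundary, H = _newton_fit(
                t[m][None], d[m][None], X[m, 1:])
            if not converged[0] and not boundary[0]:
                raise ConvergenceError("stratified Weibull fit did not converge",
                                       context=f"arm={a}")
            self.boundary_ |= bool(boundary[0])
            alphas[a], lks[a] = theta[0, 0], theta[0, 1]
            betas[a] = theta[0, 2:]
            self.vcov_by_arm_[a] = _vcov_from_hessian(H)[0]
            self.loglik_ += float(ll[0])
        self.alpha_by_arm_ = alphas
        self.log_kappa_by_arm_ = lks
        self.kappa_by_arm_ = np.exp(lks)
        self.beta_by_arm_ = betas

    # ------------------------------------------------------------- predicts
    def _eta_kappa(self, arm, covariates, theta=None):
        """Linear predictor and shape for given arm values / covariates.

        ``theta`` overrides the MLE (same layout as the fitted parameters);
        used by the imputation machinery with posterior draws.
        """
        arm = np.asarray(arm)
        cov = np.atleast_2d(np.asarray(covariates, float)) if covariates is not None \
            else np.empty((np.size(arm), 0))
        if self.stratify_by_arm:
            if theta is None:
                al, lk = self.alpha_by_arm_, self.log_kappa_by_arm_
                be = self.beta_by_arm_
            else:
                al = np.array([theta[0][0], theta[1][0]])
                lk = np.array([theta[0][1], theta[1][1]])
                be = np.vstack([theta[0][2:], theta[1][2:]])
            a = arm.astype(int)
            eta = al[a].astype(float)
            if cov.shape[1]:
                eta = eta + np.einsum("np,np->n", cov, be[a])
            return eta, np.exp(lk[a])
        th = self.theta_ if theta is None else np.asarray(theta, float)
        if getattr(self, "single_arm_", False):
            eta = th[0] + (cov @ th[2:] if cov.shape[1] else 0.0)
        else:
            eta = th[0] + th[2] * arm.astype(float) + \
                (cov @ th[3:] if cov.shape[1] > 0 else 0.0)
        kappa = np.exp(th[1]) * np.ones(np.size(arm))
        return np.asarray(eta, float) * np.ones(np.size(arm)), kappa

    def cumulative_hazard(self, t, arm, covariates=None):
        """H(t | arm, covariates) at the MLE, vectorised over subjects."""
        t = np.asarray(t, float)
        if (t < 0).any():
            raise ValueError("t must be nonnegative")
        eta, kappa = self._eta_kappa(arm, covariates)
        return t ** kappa * np.exp(eta)  # 0**kappa = 0 gives H(0)=0, S(0)=1

    def survival_function(self, t, arm, covariates=None):
        """S(t) = exp(-H(t)); S(0) = 1, strictly decreasing in t."""
        return np.exp(-self.cumulative_hazard(t, arm, covariates))

    def predict(self, X):
        """Risk score: linear predictor eta (higher = higher hazard)."""
        X = np.asarray(X, float)
        eta, _ = self._eta_kappa(X[:, 0], X[:, 1:])
        return eta

    def score(self, X, y):
        """Mean log-likelihood per subject (sklearn convention: higher better)."""
        X = np.asarray(X, float)
        t, d = self._split_y(y)
        if self.stratify_by_arm:
            tot = 0.0
            for a in (0, 1):
                m = X[:, 0] == a
                th = np.concatenate([[self.alpha_by_arm_[a],
                                      self.log_kappa_by_arm_[a]],
                                     self.beta_by_arm_[a]])
                tot += censored_weibull_loglik(th, t[m], d[m], X[m, 1:])
            return tot / len(t)
        Z = X[:, 1:] if getattr(self, "single_arm_", False) else X
        return censored_weibull_loglik(self.theta_, t, d, Z) / len(t)

    # ----------------------------------------------------------- draws
    def draw_parameters(self, random_state=None, size=None):
        """Draw from N(theta_hat, vcov) on the (alpha, log kappa, beta) scale.

        Proper-imputation step: one draw per imputation round. ``size=None``
        returns a single vector; an integer returns (size, q). For stratified
        fits a dict {arm: draw} of independent per-arm draws is returned.
        """
        rng = np.random.default_rng(random_state) \
            if not isinstance(random_state, np.random.Generator) else random_state
        if self.stratify_by_arm:
            out = {}
            for a in (0, 1):
                mean = np.concatenate([[self.alpha_by_arm_[a],
                                        self.log_kappa_by_arm_[a]],
                                       self.beta_by_arm_[a]])
                out[a] = _mvn_draw(mean, self.vcov_by_arm_[a], rng, size)
            return out
        return _mvn_draw(self.theta_, self.vcov_, rng, size)


def _mvn_draw(mean, cov, rng, size=None):
    """Multivariate-normal draw via eigen factorisation with PSD clipping."""
    cov = 0.5 * (cov + cov.T)
    w, V = np.linalg.eigh(cov)
    tol = 1e-10 * max(1.0, float(np.abs(w).max()))
    if (w < -tol).any():
        raise MatrixError("covariance matrix is not positive semi-definite")
    L = V * np.sqrt(np.clip(w, 0.0, None))
    n = 1 if size is None else int(size)
    z = rng.standard_normal((n, len(mean)))
    draws = mean + z @ L.T
    return draws[0] if size is None else draws


# ----------------------------------------------------------------- wrappers
def fit_weibull_ph(data: SurvivalData, stratify_by_arm: bool = False) -> WeibullPH:
    """Fit the Weibull PH model to a :class:`SurvivalData` dataset."""
    model = WeibullPH(stratify_by_arm=stratify_by_arm)
    return model.fit(data.design_matrix(), (data.times, data.events.astype(float)))


def survivor(fit: WeibullPH, t, arm, covariates=None):
    """Survivor function S(t | arm, covariates) of a fitted model."""
    t_arr = np.asarray(t, float)
    if (t_arr < 0).any():
        raise ValueError("t must be nonnegative")
    one = np.ones(np.size(np.asarray(arm)))
    return fit.survival_function(t_arr * one if t_arr.ndim == 0 else t_arr,
                                 np.asarray(arm), covariates)


def fit_report(fit: WeibullPH) -> str:
    """Plain-text report of a fit (parameters, covariance, log-likelihood)."""
    lines = ["Weibull proportional-hazards fit",
             f"  events: {fit.n_events_}", f"  loglik: {fit.loglik_:.6f}"]
    if fit.stratify_by_arm:
        for a in (0, 1):
            lines.append(
                f"  arm {a}: alpha={fit.alpha_by_arm_[a]:+.6f} "
                f"log_kappa={fit.log_kappa_by_arm_[a]:+.6f} "
                f"beta={np.array2string(fit.beta_by_arm_[a], precision=6)}")
    else:
        lines.append(f"  alpha={fit.alpha_:+.6f} log_kappa={fit.log_kappa_:+.6f}")
        lines.append(f"  beta={np.array2string(fit.beta_, precision=6)}")
        lines.append("  vcov (alpha, log kappa, beta):")
        for row in fit.vcov_:
            lines.append("    " + " ".join(f"{v:+.6e}" for v in row))
    return "\n".join(lines)
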