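"""Rubin's rules: combine K per-imputation estimates into one inference.

For estimates b_1..b_K with model-based variances v_1..v_K:

    beta_bar = mean(b_k)
    W        = mean(v_k)                         within-imputation variance
    B        = sample variance of b_k (K-1)      between-imputation variance
    V_RR     = W + (1 + 1/K) B                   total variance
    df       = (K-1) * (1 + W / ((1+1/K) B))**2  (infinite when B = 0)

with a t(df) reference distribution for the interval and p-value. The
optional Barnard-Rubin adjustment shrinks df using the complete-data degrees
of freedom; off by default since the intended simulations have large n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import SpecificationError


@dataclass(frozen=True)
class PooledEstimate:
    """Pooled log-hazard-ratio inference from K imputations."""

    beta_bar: float
    W: float
    B: float
    V_RR: float
    df: float
    ci_low: float
    ci_high: float
    p_value: float
    K: int
    level: float = 0.95

    @property
    def se(self) -> float:
        return float(np.sqrt(self.V_RR))

    @property
    def hazard_ratio(self) -> float:
        """Pooling is done on the log HR scale; exponentiate for the HR."""
        return float(np.exp(self.beta_bar))

    @property
    def hr_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def pool(estimates, variances, level: float = 0.95,
         barnard_rubin: bool = False,
         n_complete: int | None = None) -> PooledEstimate:
    """Combine per-imputation estimates and variances by Rubin's rules.

    Parameters
    ----------
    estimates, variances : array-like, length K >= 2
        Point estimates (log hazard ratios) and their model-based variances.
    level : float, default 0.95
        Confidence level of the interval.
    barnard_rubin : bool, default False
        Apply the Barnard-Rubin small-sample degrees-of-freedom adjustment;
        requires ``n_complete`` (complete-data sample size minus the number
        of fitted parameters).
    """
    b = np.asarray(estimates, float)
    v = np.asarray(variances, float)
    if b.ndim != 1 or b.shape != v.shape:
        raise SpecificationError("estimates and variances must be equal-length "
                                 "1-d vectors")
    K = b.size
    if K < 2:
        raise SpecificationError("Rubin's rules require K >= 2 imputations")
    if not np.isfinite(b).all() or not np.isfinite(v).all() or (v < 0).any():
        raise SpecificationError("estimates/variances must be finite, "
                                 "variances nonnegative")

    beta_bar = float(b.mean())
    W = float(v.mean())
    B = float(b.var(ddof=1))
    V = W + (1.0 + 1.0 / K) * B

    if B == 0.0:
        df = np.inf
    else:
        r = (1.0 + 1.0 / K) * B
        df = (K - 1.0) * (1.0 + W / r) ** 2
        if barnard_rubin:
            if n_complete is None:
                raise SpecificationError("barnard_rubin=True requires n_complete")
            lam = r / V
            df_obs = (n_complete + 1.0) / (n_complete + 3.0) * n_complete * (1 - lam)
            df = 1.0 / (1.0 / df + 1.0 / df_obs)

    se = np.sqrt(V)
    tq = stats.t.ppf(1.0 - (1.0 - level) / 2.0, df) if np.isfinite(df) \
        else stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    if se > 0:
        tstat = beta_bar / se
        p = 2.0 * (stats.t.sf(abs(tstat), df) if np.isfinite(df)
                   else stats.norm.sf(abs(tstat)))
    else:
        p = 0.0 if beta_bar != 0 else 1.0
    return PooledEstimate(
        beta_bar=beta_bar, W=W, B=B, V_RR=float(V), df=float(df),
        ci_low=float(beta_bar - tq * se), ci_high=float(beta_bar + tq * se),
        p_value=float(min(p, 1.0)), K=K, level=level,
    )
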