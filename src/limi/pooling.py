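"""Rubin's rules: pooling per-imputation estimates into one inference.

Given M point estimates Q_1..Q_M with model variances U_1..U_M,
    Qbar = mean(Q),  W = mean(U),  B = var(Q),  T = W + (1 + 1/M) B,
with the Barnard-Rubin small-sample degrees of freedom (which uses the
complete-data degrees of freedom) driving the t-based confidence interval.
Rubin's original large-sample df is also computed and reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PooledResult:
    """Rubin's-rules quantities for one scalar parameter."""

    m: int
    qbar: float
    w: float           # within-imputation variance
    b: float           # between-imputation variance
    t: float           # total variance
    df: float          # Barnard-Rubin adjusted degrees of freedom
    df_rubin: float    # Rubin's original large-sample df (logged alongside)
    se: float
    level: float
    ci_low: float
    ci_high: float

    def summary(self) -> str:
        return (
            f"pooled estimate {self.qbar:.4g} (SE {self.se:.4g}, "
            f"{100 * self.level:.0f}% CI [{self.ci_low:.4g}, {self.ci_high:.4g}], "
            f"df {self.df:.1f}; M={self.m}, W={self.w:.4g}, B={self.b:.4g})"
        )


def pool(
    estimates,
    variances,
    df_complete: float,
    level: float = 0.95,
) -> PooledResult:
    """Combine per-imputation estimates and variances by Rubin's rules.

    Parameters
    ----------
    estimates, variances
        Length-M vectors of point estimates and squared standard errors.
    df_complete
        Complete-data degrees of freedom of the analysis model (enters the
        Barnard-Rubin adjustment).
    level
        Confidence level of the pooled interval.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length vectors")
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(u))):
        raise ValueError("non-finite estimates or variances")
    if np.any(u <= 0):
        raise ValueError("variances must be positive")
    if df_complete <= 0:
        raise ValueError("df_complete must be positive")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    m = q.shape[0]
    if m < 1:
        raise ValueError("need at least one imputation")
    qbar = float(q.mean())
    w = float(u.mean())
    if m == 1:
        warnings.warn(
            "pooling a single imputation: between-imputation variance "
            "is undefined and set to 0",
            stacklevel=2,
        )
        b = 0.0
    else:
        b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b

    lam = (1.0 + 1.0 / m) * b / t if t > 0 else 0.0
    if b > 0 and m > 1:
        df_rubin = (m - 1) / lam**2
    else:
        df_rubin = np.inf
    df_obs = (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - lam)
    df = 1.0 / (1.0 / df_rubin + 1.0 / df_obs) if np.isfinite(df_rubin) else df_obs

    se = float(np.sqrt(t))
    tq = stats.t.ppf(0.5 + level / 2.0, df)
    return PooledResult(
        m=m,
        qbar=qbar,
        w=w,
        b=b,
        t=t,
        df=float(df),
        df_rubin=float(df_rubin),
        se=se,
        level=level,
        ci_low=qbar - tq * se,
        ci_high=qbar + tq * se,
    )


def coverage_indicator(pooled: PooledResult, truth: float) -> bool:
    """Whether the pooled confidence interval contains the true value."""
    return bool(pooled.ci_low <= truth <= pooled.ci_high)
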