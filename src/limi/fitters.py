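"""Substantive analysis-model fits used by the simulation harness.

Standard maximum-likelihood / least-squares fits go through statsmodels.
The proportional-odds ordered logit is fitted by a small constrained MLE of
our own: the cut-points are parameterised through non-negative gaps, so a
category with zero observed frequency is handled by letting the adjacent
cut-points coincide (statsmodels' OrderedModel cannot represent a declared
but empty category, which arises in the ordinal simulation scenario).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit, logit


class FitFailure(RuntimeError):
    """A substantive fit did not converge (e.g. separation); the caller
    excludes the replication and counts the event."""


@dataclass(frozen=True)
class FitResult:
    """Point estimates, model-based SEs and complete-data df of one fit."""

    params: np.ndarray
    se: np.ndarray
    df_complete: float
    names: tuple[str, ...]


MODELS = ("ols", "ols_cat4", "logistic", "multinomial", "ordered_logit", "poisson")

_MAX_ABS_COEF = 50.0


def _design(df: pd.DataFrame, categorical_x1: bool) -> tuple[np.ndarray, tuple[str, ...]]:
    n = len(df)
    x2 = df["x2"].to_numpy(dtype=float)
    if categorical_x1:
        x1 = df["x1"].to_numpy()
        X = np.column_stack(
            [np.ones(n), x1 == 2, x1 == 3, x1 == 4, x2]
        ).astype(float)
        names = ("b0", "b1", "b2", "b3", "b4")
    else:
        X = np.column_stack([np.ones(n), df["x1"].to_numpy(dtype=float), x2])
        names = ("b0", "b1", "b2")
    return X, names


def _check(params: np.ndarray, se: np.ndarray) -> None:
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(se))):
        raise FitFailure("non-finite estimates")
    if np.any(np.abs(params) > _MAX_ABS_COEF):
        raise FitFailure("diverged estimates (likely separation)")


def fit_substantive(model_id: str, df: pd.DataFrame) -> FitResult:
    """Fit the analysis model of a scenario to one complete dataset.

    ``df`` must be complete; for a complete-records analysis the caller
    drops incomplete rows first.
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown analysis model {model_id!r}")
    if df.isna().to_numpy().any():
        raise ValueError("analysis dataset contains missing values")
    n = len(df)
    y = df["y"].to_numpy(dtype=float)

    if model_id in ("ols", "ols_cat4"):
        X, names = _design(df, model_id == "ols_cat4")
        if n <= X.shape[1] + 1:
            raise FitFailure("too few rows for the OLS design")
        res = sm.OLS(y, X).fit()
        _check(res.params, res.bse)
        return FitResult(res.params, res.bse, float(res.df_resid), names)

    if model_id == "logistic":
        X, names = _design(df, False)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparation and friends
            raise FitFailure(str(exc)) from exc
        if not res.mle_retvals.get("converged", False):
            raise FitFailure("logit did not converge")
        _check(res.params, res.bse)
        return FitResult(res.params, res.bse, float(n - X.shape[1]), names)

    if model_id == "poisson":
        X, names = _design(df, False)
        try:
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=200)
        except Exception as exc:
            raise FitFailure(str(exc)) from exc
        _check(res.params, res.bse)
        return FitResult(
            np.asarray(res.params), np.asarray(res.bse), float(n - X.shape[1]), names
        )

    if model_id == "multinomial":
        return _fit_multinomial(df)
    return _fit_ordered_logit(df)


def _fit_multinomial(df: pd.DataFrame) -> FitResult:
    """Baseline-category (level 1) multinomial logit on x1, x2."""
    X, _ = _design(df, False)
    codes = df["y"].to_numpy(dtype=int)
    if not np.array_equal(np.unique(codes), np.arange(1, 5)):
        raise FitFailure("multinomial outcome does not span levels 1..4")
    try:
        res = sm.MNLogit(codes, X).fit(method="newton", disp=0, maxiter=200)
    except Exception as exc:
        raise FitFailure(str(exc)) from exc
    if not res.mle_retvals.get("converged", False):
        raise FitFailure("multinomial logit did not converge")
    params = np.asarray(res.params).T.ravel()  # contrast-major: 2v1, 3v1, 4v1
    se = np.asarray(res.bse).T.ravel()
    _check(params, se)
    names = tuple(
        f"{lvl}v1:{c}" for lvl in (2, 3, 4) for c in ("b0", "b1", "b2")
    )
    return FitResult(params, se, float(len(df) - X.shape[1]), names)


# ---------------------------------------------------------------------------
# proportional-odds ordered logit

def _ologit_nll(a: np.ndarray, b: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    """Negative log likelihood in the cumulative parameterisation
    P(Y >= j) = expit(a_j + x'b), j = 2..T, with a non-increasing."""
    eta = X @ b
    cums = expit(a[None, :] + eta[:, None])          # (n, T-1)
    probs = np.column_stack(
        [1.0 - cums[:, 0], -np.diff(cums, axis=1), cums[:, -1]]
    )
    p = probs[np.arange(y.shape[0]), y - 1]
    return -float(np.sum(np.log(np.clip(p, 1e-12, None))))


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = x.shape[0]
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h * h)
    return H


def _fit_ordered_logit(df: pd.DataFrame, n_levels: int = 4) -> FitResult:
    """Constrained MLE of the proportional-odds model.

    Internally the cut-points are (a_T, gaps >= 0) so the ordering
    a_2 >= ... >= a_T always holds; when a category has zero observed
    frequency the maximiser sits on the boundary and the two adjacent
    cut-points coincide.
    """
    y = df["y"].to_numpy(dtype=int)
    if y.min() < 1 or y.max() > n_levels:
        raise FitFailure(f"ordinal outcome outside 1..{n_levels}")
    X = np.column_stack([df["x1"].to_numpy(float), df["x2"].to_numpy(float)])
    n, k = X.shape
    T = n_levels

    cum = np.clip(
        [np.mean(y >= j) for j in range(2, T + 1)], 0.5 / n, 1 - 0.5 / n
    )
    a0 = logit(cum)
    theta0 = np.concatenate(
        [[a0[-1]], np.maximum(-np.diff(a0)[::-1], 1e-3), np.zeros(k)]
    )

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a_T, gaps, b = theta[0], theta[1 : T - 1], theta[T - 1 :]
        a = a_T + np.concatenate([np.cumsum(gaps[::-1])[::-1], [0.0]])
        return a, b

    def objective(theta: np.ndarray) -> float:
        a, b = unpack(theta)
        return _ologit_nll(a, b, y, X)

    bounds = [(None, None)] + [(0.0, None)] * (T - 2) + [(None, None)] * k
    res = optimize.minimize(
        objective, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500},
    )
    if not res.success or not np.isfinite(res.fun):
        raise FitFailure(f"ordered logit did not converge: {res.message}")
    a_hat, b_hat = unpack(res.x)
    params = np.concatenate([a_hat, b_hat])
    _check(params, np.zeros_like(params))

    def nll_free(p: np.ndarray) -> float:
        return _ologit_nll(p[: T - 1], p[T - 1 :], y, X)

    H = _numerical_hessian(nll_free, params)
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    names = tuple(f"b0{j}" for j in range(2, T + 1)) + tuple(
        f"b{i}" for i in range(1, k + 1)
    )
    return FitResult(params, se, float(n - params.shape[0]), names)
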