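"""Data-augmentation MCMC for the constrained joint normal model.

One sweep alternates: (i) rejection-sampling refresh of the latent normals
behind every *observed* binary/categorical cell, (ii) conditional-normal
draws of all working columns belonging to missing cells, (iii) a conjugate
draw of the intercept vector beta under a flat prior, and (iv) an
element-wise Metropolis-Hastings update of the constrained covariance
matrix Omega (flat prior on the free entries subject to positive
definiteness, fixed entries never proposed).

Vectorisation notes: all units share Omega, so the Schur-complement
conditional covariance of a column subset given the rest is computed once
per sweep and only the conditional means vary by row.  Missing cells are
drawn jointly per missingness pattern; latent blocks are refreshed per
variable with a shrinking active set in the rejection loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .variables import FREE, LatentLayout, decode_matrix

#: default cap on rejection-sampling attempts per cell per sweep
REJECTION_CAP = 1000


@dataclass
class MCMCState:
    """Complete working matrix, parameters and sampler bookkeeping."""

    zmat: np.ndarray                 # (N, P) continuous values + latents, no gaps
    beta: np.ndarray                 # (P,)
    omega: np.ndarray                # (P, P) SPD, honouring the constraint mask
    layout: LatentLayout
    miss_mask: np.ndarray            # (N, K) True where the cell was missing
    obs_codes: list                  # per variable: int codes (-1 if missing) or None
    rng: np.random.Generator
    free_entries: list = field(default_factory=list)   # upper-tri (i, j) free in Omega
    proposal_sd: np.ndarray | None = None
    accept_count: np.ndarray | None = None
    attempt_count: np.ndarray | None = None
    reject_cap_hits: int = 0
    patterns: list = field(default_factory=list)       # (rows, obs_cols, miss_cols)

    def __post_init__(self) -> None:
        if not self.free_entries:
            m = self.layout.mask
            self.free_entries = [
                (i, j)
                for i in range(m.shape[0])
                for j in range(i, m.shape[1])
                if m[i, j] == FREE
            ]
        nf = len(self.free_entries)
        if self.proposal_sd is None:
            self.proposal_sd = np.full(nf, 0.1)
        if self.accept_count is None:
            self.accept_count = np.zeros(nf, dtype=np.int64)
        if self.attempt_count is None:
            self.attempt_count = np.zeros(nf, dtype=np.int64)
        if not self.patterns:
            self.patterns = _missingness_patterns(self.miss_mask, self.layout)

    @property
    def n_units(self) -> int:
        return self.zmat.shape[0]

    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(
                self.attempt_count > 0,
                self.accept_count / np.maximum(self.attempt_count, 1),
                np.nan,
            )

    def reset_counters(self) -> None:
        self.accept_count[:] = 0
        self.attempt_count[:] = 0


def _missingness_patterns(miss_mask: np.ndarray, layout: LatentLayout) -> list:
    """Group rows by their per-variable missingness pattern.

    Returns (row_indices, observed_columns, missing_columns) triples for the
    patterns with at least one missing variable.  Patterns are fixed over
    the whole run, so this is computed once.
    """
    patterns = []
    if miss_mask.size == 0:
        return patterns
    uniq, inverse = np.unique(miss_mask, axis=0, return_inverse=True)
    for p, pat in enumerate(uniq):
        if not pat.any():
            continue
        rows = np.flatnonzero(inverse == p)
        miss_cols: list[int] = []
        obs_cols: list[int] = []
        for k in range(layout.n_vars):
            cols = list(range(*layout.spans[k]))
            (miss_cols if pat[k] else obs_cols).extend(cols)
        patterns.append((rows, np.asarray(obs_cols), np.asarray(miss_cols)))
    return patterns


def conditional_normal(
    mu: np.ndarray,
    sigma: np.ndarray,
    known_idx: np.ndarray,
    known_vals: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the remaining coordinates of a MVN.

    Returns the Schur-complement mean and covariance of the coordinates not
    in ``known_idx`` given the values ``known_vals`` at ``known_idx``.  The
    conditional covariance does not depend on ``known_vals``.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    P = mu.shape[0]
    known_idx = np.asarray(known_idx, dtype=int)
    free_idx = np.setdiff1d(np.arange(P), known_idx)
    if free_idx.size == 0:
        raise ValueError("all coordinates are known; nothing to condition")
    A, cond_cov = _schur(sigma, free_idx, known_idx)
    if known_idx.size == 0:
        return mu[free_idx], cond_cov
    mean = mu[free_idx] + A @ (np.asarray(known_vals, float) - mu[known_idx])
    return mean, cond_cov


def _schur(
    sigma: np.ndarray, target_idx: np.ndarray, given_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Regression matrix A = S_tg S_gg^-1 and conditional covariance."""
    Stt = sigma[np.ix_(target_idx, target_idx)]
    if given_idx.size == 0:
        return np.zeros((target_idx.size, 0)), Stt
    Stg = sigma[np.ix_(target_idx, given_idx)]
    Sgg = sigma[np.ix_(given_idx, given_idx)]
    A = np.linalg.solve(Sgg, Stg.T).T
    cond = Stt - A @ Stg.T
    # symmetrise against round-off
    return A, 0.5 * (cond + cond.T)


def _chol_or_none(mat: np.ndarray) -> np.ndarray | None:
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        return None


def draw_beta(state: MCMCState) -> MCMCState:
    """Conjugate draw of beta | zmat, Omega under a flat prior.

    The full conditional is N(column means of zmat, Omega / N).
    """
    N = state.n_units
    if N == 0:
        raise ValueError("cannot draw beta with zero units")
    L = _chol_or_none(state.omega)
    if L is None:
        raise linalg.LinAlgError("current Omega is not positive definite")
    eps = state.rng.standard_normal(state.beta.shape[0])
    state.beta = state.zmat.mean(axis=0) + (L @ eps) / np.sqrt(N)
    return state


def _resid_loglik(L: np.ndarray, S: np.ndarray, N: int) -> float:
    """Multivariate-normal residual log likelihood up to a constant.

    ``L`` is the lower Cholesky factor of Omega and ``S`` the residual
    scatter matrix sum_i (z_i - beta)(z_i - beta)'.
    """
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    half = linalg.solve_triangular(L, S, lower=True, check_finite=False)
    tr = np.trace(linalg.solve_triangular(L, half.T, lower=True, check_finite=False))
    return -0.5 * (N * logdet + tr)


def update_omega_mh(state: MCMCState) -> MCMCState:
    """Element-wise random-walk Metropolis update of the free Omega entries.

    Each free entry is visited once in a fixed order; a symmetric Gaussian
    increment is proposed, proposals breaking positive definiteness are
    rejected outright, and otherwise the move is accepted with the residual
    likelihood ratio.  Fixed entries (latent variances 1, within-block
    covariances 0.5) are never touched.
    """
    if not state.free_entries:
        return state
    N = state.n_units
    resid = state.zmat - state.beta
    S = resid.T @ resid
    omega = state.omega
    L = _chol_or_none(omega)
    if L is None:
        raise linalg.LinAlgError("current Omega is not positive definite")
    ll = _resid_loglik(L, S, N)
    increments = state.rng.standard_normal(len(state.free_entries))
    log_u = np.log(state.rng.random(len(state.free_entries)))
    for e, (i, j) in enumerate(state.free_entries):
        state.attempt_count[e] += 1
        old = omega[i, j]
        new = old + state.proposal_sd[e] * increments[e]
        if i == j and new <= 0:
            continue
        omega[i, j] = new
        omega[j, i] = new
        Lp = _chol_or_none(omega)
        if Lp is None:
            omega[i, j] = old
            omega[j, i] = old
            continue
        ll_new = _resid_loglik(Lp, S, N)
        if log_u[e] < ll_new - ll:
            ll = ll_new
            state.accept_count[e] += 1
        else:
            omega[i, j] = old
            omega[j, i] = old
    return state


def adapt_proposals(
    state: MCMCState, low: float = 0.3, high: float = 0.5, factor: float = 1.5
) -> None:
    """Multiplicative proposal-scale adjustment towards a 30-50% acceptance.

    Meant to be called periodically during burn-in only; the scales are
    frozen afterwards so the post-burn-in chain satisfies detailed balance.
    Counters are reset after each adjustment.
    """
    rates = state.acceptance_rates()
    for e, r in enumerate(rates):
        if not np.isfinite(r):
            continue
        if r > high:
            state.proposal_sd[e] *= factor
        elif r < low:
            state.proposal_sd[e] /= factor
    state.reset_counters()


def draw_latents_rejection(
    state: MCMCState,
    k: int,
    rows: np.ndarray | None = None,
    max_attempts: int = REJECTION_CAP,
) -> MCMCState:
    """Refresh the latent block of variable ``k`` for observed cells.

    For every unit whose cell is observed, the block is drawn from its
    conditional normal given all other working columns of the row,
    repeatedly until it decodes to the observed code.  Units that exhaust
    ``max_attempts`` retain their previous (already consistent) block and
    are counted in ``reject_cap_hits``.
    """
    spec = state.layout.specs[k]
    if not spec.is_latent:
        raise ValueError(f"variable {spec.name!r} has no latent block")
    if rows is None:
        rows = np.flatnonzero(~state.miss_mask[:, k])
    if rows.size == 0:
        return state
    cols = state.layout.columns(k)
    rest = np.setdiff1d(np.arange(state.layout.n_cols), cols)
    A, cond_cov = _schur(state.omega, cols, rest)
    Lc = _chol_or_none(cond_cov)
    if Lc is None:
        raise linalg.LinAlgError("conditional covariance not positive definite")
    if rest.size:
        means = state.beta[cols] + (state.zmat[np.ix_(rows, rest)] - state.beta[rest]) @ A.T
    else:
        means = np.broadcast_to(state.beta[cols], (rows.size, cols.size)).copy()
    codes = state.obs_codes[k][rows]
    active = np.arange(rows.size)
    d = cols.size
    # proposals are drawn in growing batches per still-inconsistent unit, so
    # the loop length scales with the log of the worst acceptance probability
    attempts = 0
    chunk = 4
    while active.size and attempts < max_attempts:
        c = min(chunk, max_attempts - attempts)
        draw = (
            means[active, None, :]
            + state.rng.standard_normal((active.size, c, d)) @ Lc.T
        )
        ok = decode_matrix(draw.reshape(-1, d), spec).reshape(active.size, c)
        ok = ok == codes[active, None]
        any_ok = ok.any(axis=1)
        if any_ok.any():
            first = ok[any_ok].argmax(axis=1)
            hit = active[any_ok]
            state.zmat[np.ix_(rows[hit], cols)] = draw[any_ok, first]
            active = active[~any_ok]
        attempts += c
        chunk = min(2 * chunk, 64)
    state.reject_cap_hits += int(active.size)
    return state


def draw_missing(state: MCMCState) -> MCMCState:
    """Joint conditional-normal draw of all missing cells, row-wise.

    Rows sharing a missingness pattern are drawn together: the working
    columns of the missing variables are sampled jointly from their
    conditional normal given the columns of the observed variables (or from
    the unconditional model when everything in the row is missing).
    Categorical/binary cells are *not* constrained here -- the cell is
    missing, so any decoded level is a valid imputation.
    """
    for rows, obs_cols, miss_cols in state.patterns:
        A, cond_cov = _schur(state.omega, miss_cols, obs_cols)
        Lc = _chol_or_none(cond_cov)
        if Lc is None:
            raise linalg.LinAlgError("conditional covariance not positive definite")
        if obs_cols.size:
            means = state.beta[miss_cols] + (
                state.zmat[np.ix_(rows, obs_cols)] - state.beta[obs_cols]
            ) @ A.T
        else:
            means = np.broadcast_to(
                state.beta[miss_cols], (rows.size, miss_cols.size)
            ).copy()
        draw = means + state.rng.standard_normal(means.shape) @ Lc.T
        state.zmat[np.ix_(rows, miss_cols)] = draw
    return state


def sweep(state: MCMCState, max_attempts: int = REJECTION_CAP) -> MCMCState:
    """One full data-augmentation update.

    Order: latent refresh for observed categorical/binary cells, joint
    draws of missing cells, conjugate beta draw, element-wise MH update of
    Omega.  Any fixed valid order yields a correct Gibbs scheme; this one
    is pinned for reproducibility.
    """
    for k, spec in enumerate(state.layout.specs):
        if spec.is_latent:
            draw_latents_rejection(state, k, max_attempts=max_attempts)
    draw_missing(state)
    draw_beta(state)
    update_omega_mh(state)
    return state
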