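"""Multiple imputation workflow: the model object, its results, and count
variable transformations.

:class:`LatentNormalModel` is built from a rectangular dataset (one row per
unit, missing cells as NaN) plus a list of :class:`~limi.variables.VariableSpec`.
``fit()`` runs the data-augmentation sampler -- burn-in, then ``m`` blocks of
between-imputation sweeps -- and returns a :class:`LatentNormalResults`
carrying the completed datasets and sampler diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mcmc
from .variables import (
    FIXED_HALF,
    FIXED_ONE,
    LatentLayout,
    VariableSpec,
    build_latent_layout,
    decode_matrix,
)


# ---------------------------------------------------------------------------
# count-variable working scales

def transform_count(values, treatment: str, log_offset: float = 0.0) -> np.ndarray:
    """Map non-negative counts to the continuous working scale."""
    x = np.asarray(values, dtype=float)
    if np.any(x[np.isfinite(x)] < 0):
        raise ValueError("count values must be non-negative")
    if treatment == "untransformed":
        return x.copy()
    if treatment == "sqrt":
        return np.sqrt(x)
    if treatment == "log":
        return np.log(x + log_offset) if log_offset else np.log(x)
    raise ValueError(f"no continuous working scale for treatment {treatment!r}")


def back_transform_count(values, treatment: str, log_offset: float = 0.0) -> np.ndarray:
    """Map imputed working-scale values back to counts.

    The inverse map is followed by truncation at 0; imputed counts are not
    rounded.  For the square-root scale the working value is truncated at 0
    before squaring (the inverse is only monotone on the non-negative axis).
    """
    z = np.asarray(values, dtype=float)
    if treatment == "untransformed":
        return np.maximum(z, 0.0)
    if treatment == "sqrt":
        return np.maximum(z, 0.0) ** 2
    if treatment == "log":
        return np.maximum(np.exp(z) - log_offset, 0.0)
    raise ValueError(f"no continuous working scale for treatment {treatment!r}")


# ---------------------------------------------------------------------------
# initialisation

_PRIOR_CAP = 1000


def _block_prior_cov(d: int) -> np.ndarray:
    """Latent-block prior covariance: unit variances, 0.5 off-diagonals."""
    R = np.full((d, d), 0.5)
    np.fill_diagonal(R, 1.0)
    return R


def _init_latent_blocks(
    codes: np.ndarray, spec: VariableSpec, rng: np.random.Generator
) -> np.ndarray:
    """Initial latent blocks: rejection from the block prior for observed
    codes, an unconstrained prior draw for missing cells."""
    d = spec.n_latent_cols
    n = codes.shape[0]
    L = np.linalg.cholesky(_block_prior_cov(d))
    out = rng.standard_normal((n, d)) @ L.T
    observed = codes >= 0
    active = np.flatnonzero(observed & (decode_matrix(out, spec) != codes))
    for _ in range(_PRIOR_CAP):
        if active.size == 0:
            break
        draw = rng.standard_normal((active.size, d)) @ L.T
        ok = decode_matrix(draw, spec) == codes[active]
        out[active[ok]] = draw[ok]
        active = active[~ok]
    for i in active:  # deterministic consistent fallback
        out[i] = -1.0
        code = codes[i]
        if spec.kind == "binary":
            if code == 1:
                out[i, 0] = 1.0
        elif code != spec.reference_level:
            out[i, spec.non_reference_levels.index(code)] = 1.0
    return out


def project_to_mask(omega: np.ndarray, layout: LatentLayout) -> np.ndarray:
    """Overwrite the fixed entries of Omega and enforce positive definiteness.

    Free cross-block covariances are shrunk multiplicatively towards zero
    until the Cholesky factorisation succeeds; the fixed pattern itself
    (block-diagonal with unit latent variances and 0.5 within-block
    covariances) is positive definite, so this terminates.
    """
    om = 0.5 * (omega + omega.T)
    om[layout.mask == FIXED_ONE] = 1.0
    om[layout.mask == FIXED_HALF] = 0.5
    free_diag = np.diag(layout.mask) == mcmc.FREE
    d = np.diag(om).copy()
    d[free_diag] = np.maximum(d[free_diag], 1e-6)
    np.fill_diagonal(om, d)
    free_off = (layout.mask == mcmc.FREE) & ~np.eye(om.shape[0], dtype=bool)
    for _ in range(200):
        if mcmc._chol_or_none(om) is not None:
            return om
        om[free_off] *= 0.9
    raise np.linalg.LinAlgError("could not produce a positive definite Omega")


def initialize(
    data: pd.DataFrame,
    layout: LatentLayout,
    rng: np.random.Generator,
    log_offsets: dict[str, float] | None = None,
) -> mcmc.MCMCState:
    """Build a valid initial MCMC state from a dataset with missing cells.

    Missing continuous/count cells are filled by draws from the observed
    empirical marginal; latent blocks for observed categorical/binary cells
    are initialised by rejection sampling from the constrained block prior;
    beta starts at the column means and Omega at the sample covariance
    projected onto the constraint mask.
    """
    log_offsets = log_offsets or {}
    N = len(data)
    K = layout.n_vars
    zmat = np.empty((N, layout.n_cols))
    miss_mask = np.zeros((N, K), dtype=bool)
    obs_codes: list[np.ndarray | None] = []
    for k, spec in enumerate(layout.specs):
        col = data[spec.name].to_numpy(dtype=float)
        missing = ~np.isfinite(col)
        miss_mask[:, k] = missing
        if missing.all():
            raise ValueError(f"column {spec.name!r} has no observed values")
        cols = layout.columns(k)
        if spec.is_latent:
            codes = np.where(missing, -1, col).astype(np.int64)
            obs_codes.append(codes)
            zmat[:, cols] = _init_latent_blocks(codes, spec, rng)
        else:
            obs_codes.append(None)
            if spec.kind == "count":
                work = transform_count(
                    col, spec.count_treatment, log_offsets.get(spec.name, 0.0)
                )
            else:
                work = col.copy()
            observed_vals = work[~missing]
            work[missing] = rng.choice(observed_vals, size=int(missing.sum()))
            zmat[:, cols[0]] = work
    beta = zmat.mean(axis=0)
    if N > 1:
        raw = np.cov(zmat.T, ddof=1).reshape(layout.n_cols, -1)
    else:
        raw = np.eye(layout.n_cols)
    omega = project_to_mask(np.nan_to_num(raw), layout)
    return mcmc.MCMCState(
        zmat=zmat,
        beta=beta,
        omega=omega,
        layout=layout,
        miss_mask=miss_mask,
        obs_codes=obs_codes,
        rng=rng,
    )


# ---------------------------------------------------------------------------
# model / results

class LatentNormalModel:
    """Joint latent-normal imputation model for one rectangular dataset.

    Parameters
    ----------
    data
        DataFrame with one column per declared variable; missing cells NaN.
    specs
        Variable declarations.  Count variables with
        ``count_treatment="categorical"`` are relabelled internally to
        consecutive levels (by observed value order) and imputed with the
        unordered categorical algorithm.
    """

    def __init__(self, data: pd.DataFrame, specs: list[VariableSpec]):
        missing_cols = [s.name for s in specs if s.name not in data.columns]
        if missing_cols:
            raise ValueError(f"dataset lacks declared columns: {missing_cols}")
        self.data = data.reset_index(drop=True)
        self.specs = list(specs)
        self._count_maps: dict[str, np.ndarray] = {}
        self._log_offsets: dict[str, float] = {}
        internal: list[VariableSpec] = []
        for s in specs:
            col = self.data[s.name].to_numpy(dtype=float)
            obs = col[np.isfinite(col)]
            if obs.size == 0:
                raise ValueError(f"column {s.name!r} has no observed values")
            self._validate_column(s, obs)
            if s.kind == "count" and s.count_treatment == "categorical":
                values = np.unique(obs)
                if values.size < 3:
                    raise ValueError(
                        f"count variable {s.name!r} has {values.size} distinct "
                        "observed values; the categorical treatment needs >= 3"
                    )
                self._count_maps[s.name] = values
                internal.append(
                    VariableSpec(s.name, "categorical", n_levels=values.size)
                )
            else:
                if s.kind == "count" and s.count_treatment == "log":
                    self._log_offsets[s.name] = 1.0 if obs.min() == 0 else 0.0
                internal.append(s)
        self.internal_specs = internal
        self.layout = build_latent_layout(internal)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, specs: list[VariableSpec]
    ) -> "LatentNormalModel":
        return cls(data, specs)

    @staticmethod
    def _validate_column(spec: VariableSpec, obs: np.ndarray) -> None:
        if spec.kind == "binary":
            bad = ~np.isin(obs, (0.0, 1.0))
        elif spec.kind == "categorical":
            bad = (obs != np.round(obs)) | (obs < 1) | (obs > spec.n_levels)
        elif spec.kind == "count":
            bad = (obs != np.round(obs)) | (obs < 0)
        else:
            return
        if bad.any():
            raise ValueError(
                f"column {spec.name!r} ({spec.kind}) contains invalid observed "
                f"values, e.g. {obs[bad][:3].tolist()}"
            )

    def _working_codes(self, spec: VariableSpec) -> pd.Series:
        """Column on the internal scale (count-as-categorical -> level codes)."""
        col = self.data[spec.name].to_numpy(dtype=float)
        if spec.name in self._count_maps:
            values = self._count_maps[spec.name]
            out = np.full_like(col, np.nan)
            obs = np.isfinite(col)
            out[obs] = np.searchsorted(values, col[obs]) + 1
            return pd.Series(out, name=spec.name)
        return pd.Series(col, name=spec.name)

    def fit(
        self,
        m: int = 20,
        burnin: int = 500,
        between: int = 500,
        seed: int | None = None,
        adapt_every: int = 25,
    ) -> "LatentNormalResults":
        """Run the sampler and return ``m`` completed datasets.

        ``burnin`` sweeps are discarded (with proposal-scale adaptation),
        then the dataset is snapshot after every ``between`` further sweeps.
        """
        if m < 1:
            raise ValueError("m must be >= 1")
        if burnin < 0 or between < 1:
            raise ValueError("need burnin >= 0 and between >= 1")
        rng = np.random.default_rng(seed)
        wdata = pd.DataFrame({s.name: self._working_codes(s) for s in self.internal_specs})
        state = initialize(wdata, self.layout, rng, self._log_offsets)
        for s in range(burnin):
            mcmc.sweep(state)
            if adapt_every and (s + 1) % adapt_every == 0:
                mcmc.adapt_proposals(state)
        state.reset_counters()
        state.reject_cap_hits = 0
        datasets = []
        for _ in range(m):
            for _ in range(between):
                mcmc.sweep(state)
            datasets.append(self._snapshot(state))
        return LatentNormalResults(
            model=self,
            datasets=datasets,
            state=state,
            settings={"m": m, "burnin": burnin, "between": between, "seed": seed},
        )

    def _snapshot(self, state: mcmc.MCMCState) -> pd.DataFrame:
        """Decode/back-transform the current state into a completed dataset.

        Observed cells are copied from the input unchanged; only originally
        missing cells carry the current draws.
        """
        out = self.data.copy()
        for k, spec in enumerate(self.layout.specs):
            missing = state.miss_mask[:, k]
            if not missing.any():
                continue
            cols = self.layout.columns(k)
            rows = np.flatnonzero(missing)
            orig = next(s for s in self.specs if s.name == spec.name)
            if spec.is_latent:
                codes = decode_matrix(state.zmat[np.ix_(rows, cols)], spec)
                if spec.name in self._count_maps:
                    vals = self._count_maps[spec.name][codes - 1]
                else:
                    vals = codes.astype(float)
                out.loc[rows, spec.name] = vals
            elif orig.kind == "count":
                z = state.zmat[rows, cols[0]]
                out.loc[rows, spec.name] = back_transform_count(
                    z, orig.count_treatment, self._log_offsets.get(spec.name, 0.0)
                )
            else:
                out.loc[rows, spec.name] = state.zmat[rows, cols[0]]
        return out


@dataclass
class LatentNormalResults:
    """Completed datasets plus sampler diagnostics from one fit."""

    model: LatentNormalModel
    datasets: list[pd.DataFrame]
    state: mcmc.MCMCState = field(repr=False)
    settings: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)

    @property
    def acceptance_rates(self) -> dict[tuple[int, int], float]:
        """Post-burn-in MH acceptance rate per free Omega entry."""
        rates = self.state.acceptance_rates()
        return {e: float(r) for e, r in zip(self.state.free_entries, rates)}

    @property
    def reject_cap_hits(self) -> int:
        return self.state.reject_cap_hits

    def run_log(self) -> dict:
        """Structured run summary (settings, acceptance, fallbacks)."""
        rates = [r for r in self.acceptance_rates.values() if np.isfinite(r)]
        return {
            "settings": dict(self.settings),
            "n_units": int(self.state.n_units),
            "n_imputations": self.m,
            "mh_acceptance": {
                f"{i},{j}": round(float(r), 4)
                for (i, j), r in self.acceptance_rates.items()
            },
            "mh_acceptance_mean": float(np.mean(rates)) if rates else None,
            "rejection_cap_hits": int(self.reject_cap_hits),
            "log_offsets": dict(self.model._log_offsets),
        }

    def summary(self) -> str:
        log = self.run_log()
        miss = self.state.miss_mask.sum(axis=0)
        lines = [
            "Latent-normal joint model multiple imputation",
            "=" * 46,
            f"units: {log['n_units']}   imputations: {self.m}",
            "settings: burnin={burnin} between={between} seed={seed}".format(
                **self.settings
            ),
            "",
            "variable        kind          missing",
        ]
        for k, spec in enumerate(self.model.layout.specs):
            lines.append(f"{spec.name:<15} {spec.kind:<13} {int(miss[k])}")
        if log["mh_acceptance_mean"] is not None:
            lines.append("")
            lines.append(
                f"MH acceptance (free Omega entries): mean "
                f"{log['mh_acceptance_mean']:.2f}"
            )
        lines.append(f"rejection-sampler cap hits: {log['rejection_cap_hits']}")
        return "\n".join(lines)


def impute(
    data: pd.DataFrame,
    specs: list[VariableSpec],
    m: int = 20,
    burnin: int = 500,
    between: int = 500,
    seed: int | None = None,
) -> list[pd.DataFrame]:
    """Convenience wrapper: fit the joint model and return the M datasets."""
    return LatentNormalModel(data, specs).fit(
        m=m, burnin=burnin, between=between, seed=seed
    ).datasets
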