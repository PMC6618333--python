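"""Simulation harness: data generation, amputation, replication and
Mean/mSE/eSE/coverage summaries.

Each scenario bundles a data-generating mechanism (a mix of latent-normal,
logistic, multinomial, ordered-logit and Poisson models over three
variables y, x1, x2), an amputation plan (MCAR and/or MAR-given-outcome),
a substantive analysis model, and multiple-imputation settings.  Running a
scenario repeats generate -> ampute -> analyse (full data,
complete records, joint-model MI with Rubin pooling) over many replications
and summarises, per parameter and method, the mean estimate, the mean
model SE (mSE), the empirical SE of the estimates (eSE) and the coverage
of nominal 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .fitters import FitFailure, fit_substantive
from .impute import LatentNormalModel
from .pooling import coverage_indicator, pool
from .variables import VariableSpec

_TRUTH_SEED = 20190314       # fixed internal seed for population-truth fits
_TRUTH_N = 1_000_000


# ---------------------------------------------------------------------------
# data-generating mechanisms (columns y, x1, x2)

def gen_latent_matching(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Joint normal with a latent triple for 4-level x1 and one latent for
    binary x2; matches the imputation model exactly.

    The binary variable is coded 1 on the negative side of its latent
    (P(x2=1) = Phi(0.1) ~ 0.54), the orientation pinned by the reference
    population values of the substantive linear model (intercept 2.51,
    binary coefficient -0.63).
    """
    mu = np.array([2.0, -0.2, 0.6, 0.0, -0.1])
    cov = np.full((5, 5), 0.5)
    np.fill_diagonal(cov, 1.0)
    cov[0, 0] = 2.0
    L = np.linalg.cholesky(cov)
    Z = mu + rng.standard_normal((n, 5)) @ L.T
    lat = Z[:, 1:4]
    top = lat.max(axis=1)
    x1 = np.where(top > 0, lat.argmax(axis=1) + 1, 4)
    x2 = (Z[:, 4] <= 0).astype(float)
    return pd.DataFrame({"y": Z[:, 0], "x1": x1.astype(float), "x2": x2})


def _gen_logistic_outcome(beta):
    def gen(n: int, rng: np.random.Generator) -> pd.DataFrame:
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        p = expit(beta[0] + beta[1] * x1 + beta[2] * x2)
        y = (rng.random(n) < p).astype(float)
        return pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    return gen


def _gen_binary_covariate(beta):
    def gen(n: int, rng: np.random.Generator) -> pd.DataFrame:
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = rng.standard_normal(n)
        y = beta[0] + beta[1] * x1 + beta[2] * x2 + rng.standard_normal(n)
        return pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    return gen


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw per row from row-wise category probabilities -> codes 1..T."""
    bad = np.flatnonzero((probs < -1e-9).any(axis=1))
    if bad.size:
        raise RuntimeError(
            f"invalid category probability at unit {bad[0]}: {probs[bad[0]]}"
        )
    cum = np.clip(probs, 0.0, None).cumsum(axis=1)
    u = rng.random(probs.shape[0]) * cum[:, -1]
    return (u[:, None] >= cum).sum(axis=1) + 1


def _gen_multinomial_outcome(coefs):
    """Baseline-category multinomial logit with category 1 as reference:
    p_j = exp(Z_j) / (1 + sum_k exp(Z_k)) for j = 2..4."""
    coefs = np.asarray(coefs, dtype=float)          # (3 contrasts, 3 coefs)

    def gen(n: int, rng: np.random.Generator) -> pd.DataFrame:
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x1, x2])
        Z = X @ coefs.T                              # (n, 3)
        eZ = np.exp(Z)
        denom = 1.0 + eZ.sum(axis=1)
        probs = np.column_stack([1.0 / denom, eZ / denom[:, None]])
        y = _sample_rows(probs, rng).astype(float)
        return pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    return gen


def _gen_categorical_covariate(probs=(0.2, 0.3, 0.4, 0.1), beta=(0.1, 0.1, -0.2, 0.05, 0.1)):
    probs = np.asarray(probs, dtype=float)

    def gen(n: int, rng: np.random.Generator) -> pd.DataFrame:
        x1 = _sample_rows(np.broadcast_to(probs, (n, 4)), rng)
        x2 = rng.standard_normal(n)
        y = (
            beta[0]
            + beta[1] * (x1 == 2)
            + beta[2] * (x1 == 3)
            + beta[3] * (x1 == 4)
            + beta[4] * x2
            + rng.standard_normal(n)
        )
        return pd.DataFrame({"y": y, "x1": x1.astype(float), "x2": x2})
    return gen


def _gen_ordinal_outcome(a=(0.1, 0.1, -0.6), b=(0.0, 0.6)):
    """Proportional-odds generation: P(Y >= j) = expit(a_j + b1 x1 + b2 x2),
    category probabilities (1-p2, p2-p3, p3-p4, p4)."""
    a = np.asarray(a, dtype=float)

    def gen(n: int, rng: np.random.Generator) -> pd.DataFrame:
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        eta = b[0] * x1 + b[1] * x2
        cums = expit(a[None, :] + eta[:, None])      # (n, 3): p2, p3, p4
        probs = np.column_stack(
            [1.0 - cums[:, 0], -np.diff(cums, axis=1), cums[:, -1]]
        )
        y = _sample_rows(probs, rng).astype(float)
        return pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    return gen


def _gen_ordinal_covariate(cuts=(-0.5, 0.0, 0.5), beta=(0.1, 0.1, 0.2, 0.3, 0.1)):
    cuts = np.asarray(cuts, dtype=float)

    def gen(n: int, rng: np.random.Generator) -> pd.DataFrame:
        z = rng.standard_normal(n)
        x1 = np.searchsorted(cuts, z) + 1
        x2 = rng.standard_normal(n)
        y = (
            beta[0]
            + beta[1] * (x1 == 2)
            + beta[2] * (x1 == 3)
            + beta[3] * (x1 == 4)
            + beta[4] * x2
            + rng.standard_normal(n)
        )
        return pd.DataFrame({"y": y, "x1": x1.astype(float), "x2": x2})
    return gen


def _gen_poisson_outcome(beta):
    def gen(n: int, rng: np.random.Generator) -> pd.DataFrame:
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        lam = np.exp(beta[0] + beta[1] * x1 + beta[2] * x2)
        y = rng.poisson(lam).astype(float)
        return pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    return gen


def _gen_count_covariate(beta=(0.3, 0.3, 0.3), mean_count=3.0):
    def gen(n: int, rng: np.random.Generator) -> pd.DataFrame:
        x1 = rng.poisson(mean_count, size=n).astype(float)
        x2 = rng.standard_normal(n)
        y = beta[0] + beta[1] * x1 + beta[2] * x2 + rng.standard_normal(n)
        return pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    return gen


# ---------------------------------------------------------------------------
# amputation

@dataclass(frozen=True)
class Mechanism:
    """Per-variable missingness mechanism."""

    kind: str                       # none | mcar | mar_logistic | mar_calibrated
    p: float | None = None          # mcar probability
    driver: str | None = None       # MAR driver variable
    a: float | None = None          # mar_logistic intercept
    b: float = 1.0                  # mar slope on the driver
    target_rate: float | None = None  # mar_calibrated expected rate

    @staticmethod
    def none() -> "Mechanism":
        return Mechanism("none")

    @staticmethod
    def mcar(p: float) -> "Mechanism":
        if not 0 <= p <= 1:
            raise ValueError("MCAR probability outside [0, 1]")
        return Mechanism("mcar", p=p)

    @staticmethod
    def mar_logistic(driver: str, a: float, b: float = 1.0) -> "Mechanism":
        return Mechanism("mar_logistic", driver=driver, a=a, b=b)

    @staticmethod
    def mar_calibrated(driver: str, target_rate: float, b: float = 1.0) -> "Mechanism":
        if not 0 < target_rate < 1:
            raise ValueError("target rate outside (0, 1)")
        return Mechanism("mar_calibrated", driver=driver, b=b, target_rate=target_rate)


@dataclass(frozen=True)
class AmputationPlan:
    """Mechanisms per variable.  MAR drivers must themselves be amputed only
    by none/MCAR mechanisms, so that missingness depends on observed data."""

    mechanisms: dict[str, Mechanism]

    def __post_init__(self) -> None:
        for var, mech in self.mechanisms.items():
            if mech.kind.startswith("mar"):
                drv = self.mechanisms.get(mech.driver, Mechanism.none())
                if drv.kind.startswith("mar"):
                    raise ValueError(
                        f"MAR driver {mech.driver!r} of {var!r} is itself MAR"
                    )


def calibrate_mar_intercept(driver, b: float, target_rate: float) -> float:
    """Intercept a with mean over the empirical driver distribution of
    1/(1+exp(a - b*driver)) equal to target_rate, found by bisection."""
    d = np.asarray(driver, dtype=float)
    lo, hi = -60.0, 60.0

    def rate(a: float) -> float:
        return float(np.mean(expit(b * d - a)))

    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if rate(mid) > target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def ampute(df: pd.DataFrame, plan: AmputationPlan, rng: np.random.Generator) -> pd.DataFrame:
    """Introduce missing cells per the plan: MCAR flags first, then MAR flags
    computed from the driver and applied only where the driver is observed."""
    out = df.copy()
    n = len(df)
    miss: dict[str, np.ndarray] = {}
    for var, mech in plan.mechanisms.items():
        if mech.kind == "mcar":
            miss[var] = rng.random(n) < mech.p
        elif mech.kind == "none":
            miss[var] = np.zeros(n, dtype=bool)
    for var, mech in plan.mechanisms.items():
        if not mech.kind.startswith("mar"):
            continue
        d = df[mech.driver].to_numpy(dtype=float)
        driver_missing = miss.get(mech.driver, np.zeros(n, dtype=bool))
        if mech.kind == "mar_calibrated":
            a = calibrate_mar_intercept(d[~driver_missing], mech.b, mech.target_rate)
        else:
            a = mech.a
        p = expit(mech.b * d - a)
        p[driver_missing] = 0.0   # mechanism conditions on an observed driver
        miss[var] = rng.random(n) < p
    for var, flags in miss.items():
        out.loc[flags, var] = np.nan
    return out


# ---------------------------------------------------------------------------
# scenario configuration and replication loop

METHODS = ("full_data", "complete_records", "jm_mi")


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to run one simulation scenario."""

    scenario: str
    generator: object                       # callable (n, rng) -> DataFrame
    n: int
    impute_specs: tuple[VariableSpec, ...]
    analysis: str
    plan: AmputationPlan
    truth: np.ndarray | None                # None -> large-sample fit
    methods: tuple[str, ...] = METHODS
    m: int = 20
    burnin: int = 500
    between: int = 500
    nrep: int = 1000
    base_seed: int = 1

    def __post_init__(self) -> None:
        if self.nrep < 1:
            raise ValueError("nrep must be >= 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")


@dataclass
class SummaryTable:
    """Per parameter x method summary of a replication run."""

    scenario: str
    frame: pd.DataFrame
    n_failed: int = 0

    COLUMNS = (
        "scenario", "method", "parameter", "truth", "mean", "mse", "ese",
        "cov", "nrep", "mc_se_mean", "mc_se_cov",
    )

    def value(self, method: str, parameter: str, column: str) -> float:
        f = self.frame
        row = f[(f.method == method) & (f.parameter == parameter)]
        if len(row) != 1:
            raise KeyError((method, parameter))
        return float(row[column].iloc[0])


_truth_cache: dict[tuple[int, str], np.ndarray] = {}


def population_truth(
    generator, analysis: str, n: int = _TRUTH_N, seed: int = _TRUTH_SEED
) -> np.ndarray:
    """True analysis-model coefficients from a large-sample fit to the
    generator's own output (used where truth is not the generating vector)."""
    key = (id(generator), analysis)
    if key not in _truth_cache:
        df = generator(n, np.random.default_rng(seed))
        _truth_cache[key] = fit_substantive(analysis, df).params
    return _truth_cache[key]


def _resolve_truth(config: ScenarioConfig) -> np.ndarray:
    if config.truth is not None:
        return np.asarray(config.truth, dtype=float)
    return population_truth(config.generator, config.analysis)


def _interval_covers(params, se, df_complete, truth) -> np.ndarray:
    tq = stats.t.ppf(0.975, df_complete)
    return np.abs(params - truth) <= tq * se


def run_replications(config: ScenarioConfig, progress: bool = False) -> SummaryTable:
    """Run the full generate -> ampute -> analyse loop and summarise.

    Replication r uses child seed base_seed + r.  A replication on which any
    requested method fails (non-convergence, separation) is excluded for all
    methods jointly; the run aborts if more than 5% of replications fail.
    """
    truth = _resolve_truth(config)
    results: dict[str, dict[str, list]] = {
        meth: {"est": [], "se": [], "cov": []} for meth in config.methods
    }
    names: tuple[str, ...] | None = None
    n_failed = 0
    for r in range(1, config.nrep + 1):
        seed = (config.base_seed + r) % (2**31)
        rng = np.random.default_rng(seed)
        full = config.generator(config.n, rng)
        amputed = ampute(full, config.plan, rng)
        rep: dict[str, tuple] = {}
        try:
            for meth in config.methods:
                if meth == "full_data":
                    fr = fit_substantive(config.analysis, full)
                    rep[meth] = (
                        fr.params, fr.se,
                        _interval_covers(fr.params, fr.se, fr.df_complete, truth),
                        fr.names,
                    )
                elif meth == "complete_records":
                    cr = amputed.dropna().reset_index(drop=True)
                    fr = fit_substantive(config.analysis, cr)
                    rep[meth] = (
                        fr.params, fr.se,
                        _interval_covers(fr.params, fr.se, fr.df_complete, truth),
                        fr.names,
                    )
                else:
                    imp_seed = int(rng.integers(2**31))
                    res = LatentNormalModel(
                        amputed, list(config.impute_specs)
                    ).fit(
                        m=config.m, burnin=config.burnin,
                        between=config.between, seed=imp_seed,
                    )
                    fits = [
                        fit_substantive(config.analysis, d) for d in res.datasets
                    ]
                    est = np.empty(len(fits[0].params))
                    se = np.empty_like(est)
                    cov = np.empty(est.shape, dtype=bool)
                    for pidx in range(est.shape[0]):
                        pooled = pool(
                            [f.params[pidx] for f in fits],
                            [f.se[pidx] ** 2 for f in fits],
                            df_complete=fits[0].df_complete,
                        )
                        est[pidx] = pooled.qbar
                        se[pidx] = pooled.se
                        cov[pidx] = coverage_indicator(pooled, truth[pidx])
                    rep[meth] = (est, se, cov, fits[0].names)
        except FitFailure:
            n_failed += 1
            continue
        for meth, (est, se, cov, nm) in rep.items():
            names = nm
            results[meth]["est"].append(est)
            results[meth]["se"].append(se)
            results[meth]["cov"].append(cov)
        if progress and r % 50 == 0:
            print(f"[{config.scenario}] replication {r}/{config.nrep}", flush=True)
    if n_failed > 0.05 * config.nrep:
        raise RuntimeError(
            f"scenario {config.scenario}: {n_failed}/{config.nrep} replications "
            "failed to fit; aborting"
        )

    rows = []
    for meth in config.methods:
        est = np.asarray(results[meth]["est"])
        se = np.asarray(results[meth]["se"])
        cov = np.asarray(results[meth]["cov"])
        R = est.shape[0]
        for pidx, pname in enumerate(names):
            ese = float(est[:, pidx].std(ddof=1)) if R > 1 else np.nan
            cv = float(cov[:, pidx].mean())
            rows.append({
                "scenario": config.scenario,
                "method": meth,
                "parameter": pname,
                "truth": float(truth[pidx]),
                "mean": float(est[:, pidx].mean()),
                "mse": float(se[:, pidx].mean()),
                "ese": ese,
                "cov": cv,
                "nrep": R,
                "mc_se_mean": ese / np.sqrt(R) if R > 1 else np.nan,
                "mc_se_cov": float(np.sqrt(cv * (1 - cv) / R)),
            })
    frame = pd.DataFrame(rows, columns=list(SummaryTable.COLUMNS))
    return SummaryTable(config.scenario, frame, n_failed)


# ---------------------------------------------------------------------------
# scenario registry

def _cont(name: str) -> VariableSpec:
    return VariableSpec(name, "continuous")


_Y_MCAR_X1_MAR = {
    "y": Mechanism.mcar(0.2),
    "x1": Mechanism.mar_calibrated("y", 0.2),
    "x2": Mechanism.mcar(0.2),
}

_EFFECT_SIZES = {"small": 0.1, "medium": 0.3, "large": 3.0}

_MULTINOM_COEFS = (
    (0.0, -0.1, 0.05),
    (0.0, -0.05, 0.0),
    (0.0, 0.05, 0.1),
)


def scenario_ids() -> tuple[str, ...]:
    return (
        "t1_mcar", "t1_mar",
        "t2_logit_small", "t2_logit_medium", "t2_logit_large",
        "t2_bincov_small", "t2_bincov_medium", "t2_bincov_large",
        "t3_multinom", "t3_catcov", "t3_ologit", "t3_ordcov",
        "t4_pois_large_small", "t4_pois_large_big", "t4_pois_small",
        "t4_countcov",
    )


def make_scenario(
    scenario_id: str,
    *,
    n: int | None = None,
    nrep: int | None = None,
    m: int | None = None,
    burnin: int | None = None,
    between: int | None = None,
    methods: tuple[str, ...] | None = None,
    treatment: str | None = None,
    seed: int = 1,
) -> ScenarioConfig:
    """Build a scenario configuration by id, with optional overrides.

    ``treatment`` selects the count working scale in the t4 scenarios.
    Defaults reproduce the reference study conditions: n=300, 1000
    replications, M=20 imputations, burn-in 500, 500 sweeps between
    imputations.
    """
    if scenario_id not in scenario_ids():
        raise ValueError(
            f"unknown scenario {scenario_id!r}; expected one of {scenario_ids()}"
        )
    treatment = treatment or "untransformed"

    if scenario_id.startswith("t1"):
        x1_mech = (
            Mechanism.mcar(0.4)
            if scenario_id == "t1_mcar"
            else Mechanism.mar_logistic("y", a=3.0, b=1.0)
        )
        cfg = ScenarioConfig(
            scenario=scenario_id,
            generator=gen_latent_matching,
            n=300,
            impute_specs=(
                _cont("y"),
                VariableSpec("x1", "categorical", n_levels=4),
                VariableSpec("x2", "binary"),
            ),
            analysis="ols_cat4",
            plan=AmputationPlan({
                "y": Mechanism.mcar(0.2),
                "x1": x1_mech,
                "x2": Mechanism.mcar(0.2),
            }),
            truth=None,   # population values of the linear model, fitted once
            base_seed=seed,
        )
    elif scenario_id.startswith("t2_logit"):
        e = _EFFECT_SIZES[scenario_id.rsplit("_", 1)[1]]
        cfg = ScenarioConfig(
            scenario=scenario_id,
            generator=_gen_logistic_outcome((e, e, e)),
            n=300,
            impute_specs=(VariableSpec("y", "binary"), _cont("x1"), _cont("x2")),
            analysis="logistic",
            plan=AmputationPlan(dict(_Y_MCAR_X1_MAR)),
            truth=np.array([e, e, e]),
            base_seed=seed,
        )
    elif scenario_id.startswith("t2_bincov"):
        e = _EFFECT_SIZES[scenario_id.rsplit("_", 1)[1]]
        cfg = ScenarioConfig(
            scenario=scenario_id,
            generator=_gen_binary_covariate((e, e, e)),
            n=300,
            impute_specs=(_cont("y"), VariableSpec("x1", "binary"), _cont("x2")),
            analysis="ols",
            plan=AmputationPlan(dict(_Y_MCAR_X1_MAR)),
            truth=np.array([e, e, e]),
            base_seed=seed,
        )
    elif scenario_id == "t3_multinom":
        cfg = ScenarioConfig(
            scenario=scenario_id,
            generator=_gen_multinomial_outcome(_MULTINOM_COEFS),
            n=300,
            impute_specs=(
                VariableSpec("y", "categorical", n_levels=4),
                _cont("x1"), _cont("x2"),
            ),
            analysis="multinomial",
            plan=AmputationPlan(dict(_Y_MCAR_X1_MAR)),
            truth=np.asarray(_MULTINOM_COEFS).ravel(),
            base_seed=seed,
        )
    elif scenario_id == "t3_catcov":
        cfg = ScenarioConfig(
            scenario=scenario_id,
            generator=_gen_categorical_covariate(),
            n=300,
            impute_specs=(
                _cont("y"),
                VariableSpec("x1", "categorical", n_levels=4),
                _cont("x2"),
            ),
            analysis="ols_cat4",
            plan=AmputationPlan(dict(_Y_MCAR_X1_MAR)),
            truth=np.array([0.1, 0.1, -0.2, 0.05, 0.1]),
            base_seed=seed,
        )
    elif scenario_id == "t3_ologit":
        cfg = ScenarioConfig(
            scenario=scenario_id,
            generator=_gen_ordinal_outcome(),
            n=300,
            impute_specs=(
                VariableSpec("y", "categorical", n_levels=4),
                _cont("x1"), _cont("x2"),
            ),
            analysis="ordered_logit",
            plan=AmputationPlan(dict(_Y_MCAR_X1_MAR)),
            truth=np.array([0.1, 0.1, -0.6, 0.0, 0.6]),
            base_seed=seed,
        )
    elif scenario_id == "t3_ordcov":
        cfg = ScenarioConfig(
            scenario=scenario_id,
            generator=_gen_ordinal_covariate(),
            n=300,
            impute_specs=(
                _cont("y"),
                VariableSpec("x1", "categorical", n_levels=4),
                _cont("x2"),
            ),
            analysis="ols_cat4",
            plan=AmputationPlan(dict(_Y_MCAR_X1_MAR)),
            truth=np.array([0.1, 0.1, 0.2, 0.3, 0.1]),
            base_seed=seed,
        )
    elif scenario_id.startswith("t4_pois"):
        beta = {
            "t4_pois_large_small": (3.0, 0.1, 0.1),
            "t4_pois_large_big": (3.0, 0.3, 0.3),
            "t4_pois_small": (-0.5, 0.1, 0.1),
        }[scenario_id]
        if treatment == "categorical" and scenario_id != "t4_pois_small":
            raise ValueError(
                "the categorical count treatment is only viable for the "
                "small-mean scenario t4_pois_small"
            )
        cfg = ScenarioConfig(
            scenario=scenario_id,
            generator=_gen_poisson_outcome(beta),
            n=300,
            impute_specs=(
                VariableSpec("y", "count", count_treatment=treatment),
                _cont("x1"), _cont("x2"),
            ),
            analysis="poisson",
            plan=AmputationPlan(dict(_Y_MCAR_X1_MAR)),
            truth=np.asarray(beta),
            base_seed=seed,
        )
    else:  # t4_countcov
        if treatment == "categorical":
            raise ValueError(
                "the count covariate scenario treats x1 as continuous "
                "(untransformed, sqrt or log)"
            )
        cfg = ScenarioConfig(
            scenario=scenario_id,
            generator=_gen_count_covariate(),
            n=300,
            impute_specs=(
                _cont("y"),
                VariableSpec("x1", "count", count_treatment=treatment),
                _cont("x2"),
            ),
            analysis="ols",
            plan=AmputationPlan(dict(_Y_MCAR_X1_MAR)),
            truth=np.array([0.3, 0.3, 0.3]),
            base_seed=seed,
        )

    overrides = {}
    for key, val in (
        ("n", n), ("nrep", nrep), ("m", m), ("burnin", burnin),
        ("between", between), ("methods", methods),
    ):
        if val is not None:
            overrides[key] = val
    return replace(cfg, **overrides) if overrides else cfg
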