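"""The data-augmentation sampler: conditionals, constraint preservation,
rejection sampling, and stationary behaviour on complete data."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from limi import VariableSpec, build_latent_layout, conditional_normal, decode_matrix
from limi.impute import initialize
from limi.mcmc import (
    draw_beta,
    draw_latents_rejection,
    draw_missing,
    sweep,
    update_omega_mh,
)
from limi.variables import FIXED_HALF, FIXED_ONE


def _state_from(df, specs, seed=0):
    layout = build_latent_layout(specs)
    return initialize(df, layout, np.random.default_rng(seed))


class TestConditionalNormal:
    def test_bivariate_hand_example(self):
        mean, cov = conditional_normal(
            np.zeros(2), np.array([[1.0, 0.5], [0.5, 1.0]]), [1], [1.0]
        )
        assert mean == pytest.approx([0.5])
        np.testing.assert_allclose(cov, [[0.75]])

    def test_diagonal_covariance_gives_marginal(self, rng):
        sigma = np.diag([2.0, 3.0, 4.0])
        mu = np.array([1.0, -1.0, 0.5])
        mean, cov = conditional_normal(mu, sigma, [0, 2], [9.0, -9.0])
        assert mean == pytest.approx([-1.0])
        np.testing.assert_allclose(cov, [[3.0]])

    def test_all_known_rejected(self):
        with pytest.raises(ValueError, match="nothing to condition"):
            conditional_normal(np.zeros(2), np.eye(2), [0, 1], [0.0, 0.0])

    @pytest.mark.parametrize("P", [2, 3, 5, 8])
    def test_matches_precision_matrix_oracle(self, P, rng):
        # independent derivation: the conditional precision is the
        # corresponding sub-block of the joint precision matrix
        A = rng.standard_normal((P, P))
        sigma = A @ A.T + P * np.eye(P)
        mu = rng.standard_normal(P)
        known = rng.choice(P, size=P // 2, replace=False)
        free = np.setdiff1d(np.arange(P), known)
        vals = rng.standard_normal(known.size)
        mean, cov = conditional_normal(mu, sigma, known, vals)
        prec = np.linalg.inv(sigma)
        cov_oracle = np.linalg.inv(prec[np.ix_(free, free)])
        mean_oracle = mu[free] - cov_oracle @ prec[np.ix_(free, known)] @ (
            vals - mu[known]
        )
        np.testing.assert_allclose(mean, mean_oracle, atol=1e-10)
        np.testing.assert_allclose(cov, cov_oracle, atol=1e-10)


class TestDrawBeta:
    def test_single_unit_posterior_is_standard_normal_around_value(self):
        df = pd.DataFrame({"y": [5.0]})
        st_ = _state_from(df, [VariableSpec("y", "continuous")], seed=1)
        st_.omega = np.array([[1.0]])
        draws = []
        for _ in range(4000):
            draw_beta(st_)
            draws.append(st_.beta[0])
        draws = np.asarray(draws)
        assert draws.mean() == pytest.approx(5.0, abs=4 / np.sqrt(4000))
        assert draws.std() == pytest.approx(1.0, abs=0.05)

    def test_posterior_centred_on_column_means(self, rng):
        df = pd.DataFrame(rng.standard_normal((500, 2)) + [1.0, -2.0], columns=["a", "b"])
        specs = [VariableSpec("a", "continuous"), VariableSpec("b", "continuous")]
        st_ = _state_from(df, specs, seed=2)
        target = st_.zmat.mean(axis=0)
        draws = np.array([draw_beta(st_).beta.copy() for _ in range(2000)])
        # posterior sd is sqrt(omega_kk / N); allow 4 MC sigmas of the average
        tol = 4 * np.sqrt(np.diag(st_.omega) / 500 / 2000)
        assert np.all(np.abs(draws.mean(axis=0) - target) < tol + 1e-12)


class TestOmegaUpdate:
    def test_fully_constrained_matrix_never_moves(self):
        df = pd.DataFrame({"b": [0.0, 1.0, 1.0, 0.0] * 5})
        st_ = _state_from(df, [VariableSpec("b", "binary")], seed=3)
        before = st_.omega.copy()
        update_omega_mh(st_)
        assert np.array_equal(st_.omega, before)
        assert st_.attempt_count.size == 0

    def test_posterior_concentrates_on_sample_covariance(self, rng):
        n = 500
        L = np.array([[1.0, 0.0], [0.6, 0.8]])
        X = rng.standard_normal((n, 2)) @ L.T + [0.5, -0.5]
        df = pd.DataFrame(X, columns=["a", "b"])
        specs = [VariableSpec("a", "continuous"), VariableSpec("b", "continuous")]
        st_ = _state_from(df, specs, seed=4)
        S = np.cov(X.T, ddof=0)
        acc = np.zeros((2, 2))
        nkeep = 0
        for s in range(1500):
            sweep(st_)
            if s >= 300:
                acc += st_.omega
                nkeep += 1
        np.testing.assert_allclose(acc / nkeep, S, atol=0.12)

    def test_accepted_states_remain_spd(self, mixed_incomplete, mixed_specs):
        _, dfm = mixed_incomplete
        st_ = _state_from(dfm, mixed_specs, seed=5)
        for _ in range(30):
            sweep(st_)
            assert np.linalg.eigvalsh(st_.omega).min() > 0


class TestRejectionSampling:
    def test_binary_observed_one_matches_truncated_normal_moment(self):
        df = pd.DataFrame({"b": np.ones(3000)})
        st_ = _state_from(df, [VariableSpec("b", "binary")], seed=6)
        st_.beta = np.zeros(1)
        st_.omega = np.array([[1.0]])
        draw_latents_rejection(st_, 0)
        z = st_.zmat[:, 0]
        assert (z > 0).all()
        # E[Z | Z > 0] for standard normal = sqrt(2/pi)
        trunc_mean = np.sqrt(2 / np.pi)
        trunc_sd = np.sqrt(1 - trunc_mean**2)
        assert z.mean() == pytest.approx(trunc_mean, abs=4 * trunc_sd / np.sqrt(3000))

    def test_reference_level_blocks_all_negative(self):
        df = pd.DataFrame({"c": np.full(500, 4.0)})
        st_ = _state_from(df, [VariableSpec("c", "categorical", n_levels=4)], seed=7)
        draw_latents_rejection(st_, 0)
        assert (st_.zmat < 0).all()

    def test_certain_acceptance_keeps_first_draw(self):
        df = pd.DataFrame({"b": np.ones(50)})
        st_ = _state_from(df, [VariableSpec("b", "binary")], seed=8)
        st_.beta = np.array([10.0])   # conditional mean +10: always consistent
        st_.omega = np.array([[1.0]])
        draw_latents_rejection(st_, 0)
        assert st_.reject_cap_hits == 0
        assert (st_.zmat > 0).all()

    def test_exhausted_attempts_retain_previous_block_and_count(self):
        df = pd.DataFrame({"b": np.ones(20)})
        st_ = _state_from(df, [VariableSpec("b", "binary")], seed=9)
        before = st_.zmat.copy()
        st_.beta = np.array([-60.0])  # acceptance probability ~ 0
        st_.omega = np.array([[1.0]])
        draw_latents_rejection(st_, 0, max_attempts=30)
        assert st_.reject_cap_hits == 20
        np.testing.assert_array_equal(st_.zmat, before)


class TestSweep:
    def test_complete_continuous_data_never_touches_zmat(self, rng):
        df = pd.DataFrame(rng.standard_normal((100, 2)), columns=["a", "b"])
        specs = [VariableSpec("a", "continuous"), VariableSpec("b", "continuous")]
        st_ = _state_from(df, specs, seed=10)
        before = st_.zmat.copy()
        for _ in range(10):
            sweep(st_)
        np.testing.assert_array_equal(st_.zmat, before)

    def test_invariants_hold_after_every_sweep(self, mixed_incomplete, mixed_specs):
        _, dfm = mixed_incomplete
        st_ = _state_from(dfm, mixed_specs, seed=11)
        layout = st_.layout
        for _ in range(25):
            sweep(st_)
            assert (st_.omega[layout.mask == FIXED_ONE] == 1.0).all()
            assert (st_.omega[layout.mask == FIXED_HALF] == 0.5).all()
            assert np.isfinite(st_.zmat).all()
            for k, spec in enumerate(layout.specs):
                if not spec.is_latent:
                    continue
                rows = np.flatnonzero(~st_.miss_mask[:, k])
                blocks = st_.zmat[np.ix_(rows, layout.columns(k))]
                codes = decode_matrix(blocks, spec)
                np.testing.assert_array_equal(codes, st_.obs_codes[k][rows])

    def test_all_missing_row_draws_from_unconditional_model(self, rng):
        df = pd.DataFrame({"a": [np.nan, 1.0, 2.0, 0.5], "b": [np.nan, 0.0, 1.0, 0.3]})
        specs = [VariableSpec("a", "continuous"), VariableSpec("b", "continuous")]
        st_ = _state_from(df, specs, seed=12)
        v0 = st_.zmat[0].copy()
        draw_missing(st_)
        assert not np.array_equal(st_.zmat[0], v0)
        assert np.isfinite(st_.zmat).all()

    def test_trajectories_are_seed_deterministic(self, mixed_incomplete, mixed_specs):
        _, dfm = mixed_incomplete
        a = _state_from(dfm, mixed_specs, seed=13)
        b = _state_from(dfm, mixed_specs, seed=13)
        for _ in range(5):
            sweep(a)
            sweep(b)
        np.testing.assert_array_equal(a.zmat, b.zmat)
        np.testing.assert_array_equal(a.omega, b.omega)
        np.testing.assert_array_equal(a.beta, b.beta)
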