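"""The multiple-imputation workflow: count scales, initialisation, and the
statistical behaviour of the completed datasets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from limi import LatentNormalModel, VariableSpec, build_latent_layout
from limi.impute import back_transform_count, initialize, transform_count
from limi.scenarios import gen_latent_matching
from limi.variables import FIXED_HALF, FIXED_ONE


class TestCountScales:
    @pytest.mark.parametrize("treatment,offset", [
        ("untransformed", 0.0), ("sqrt", 0.0), ("log", 1.0), ("log", 0.0),
    ])
    def test_forward_backward_inverse_pair_on_counts(self, treatment, offset):
        x = np.arange(10, dtype=float)
        if treatment == "log" and offset == 0.0:
            x = x[1:]  # log without offset needs positive counts
        z = transform_count(x, treatment, offset)
        np.testing.assert_allclose(back_transform_count(z, treatment, offset), x, atol=1e-12)

    def test_sqrt_example(self):
        assert transform_count([9.0], "sqrt")[0] == 3.0
        assert back_transform_count([3.0], "sqrt")[0] == 9.0

    def test_back_transform_truncates_at_zero_without_rounding(self):
        out = back_transform_count([-0.4, 2.7], "untransformed")
        assert out[0] == 0.0
        assert out[1] == 2.7           # non-integers are kept
        assert back_transform_count([-3.0], "sqrt")[0] == 0.0
        assert back_transform_count([-20.0], "log", 1.0)[0] == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            transform_count([-1.0], "sqrt")

    def test_categorical_treatment_has_no_continuous_scale(self):
        with pytest.raises(ValueError, match="working scale"):
            transform_count([1.0], "categorical")

    @given(st.lists(st.integers(0, 500), min_size=1, max_size=20))
    def test_roundtrip_property_on_integer_counts(self, counts):
        x = np.asarray(counts, dtype=float)
        for treatment, off in (("untransformed", 0.0), ("sqrt", 0.0), ("log", 1.0)):
            z = transform_count(x, treatment, off)
            np.testing.assert_allclose(
                back_transform_count(z, treatment, off), x, atol=1e-9
            )


class TestInitialize:
    def test_complete_data_preserved_and_consistent(self, mixed_specs, rng):
        df = gen_latent_matching(80, rng)
        layout = build_latent_layout(mixed_specs)
        state = initialize(df, layout, np.random.default_rng(0))
        np.testing.assert_array_equal(state.zmat[:, 0], df["y"].to_numpy())
        from limi.variables import decode_matrix
        codes = decode_matrix(state.zmat[:, 1:4], mixed_specs[1])
        np.testing.assert_array_equal(codes, df["x1"].to_numpy().astype(int))

    def test_initial_omega_honours_mask_and_is_spd(self, mixed_incomplete, mixed_specs):
        _, dfm = mixed_incomplete
        layout = build_latent_layout(mixed_specs)
        state = initialize(dfm, layout, np.random.default_rng(0))
        assert (state.omega[layout.mask == FIXED_ONE] == 1.0).all()
        assert (state.omega[layout.mask == FIXED_HALF] == 0.5).all()
        assert np.linalg.eigvalsh(state.omega).min() > 0

    def test_seed_determinism(self, mixed_incomplete, mixed_specs):
        _, dfm = mixed_incomplete
        layout = build_latent_layout(mixed_specs)
        a = initialize(dfm, layout, np.random.default_rng(42))
        b = initialize(dfm, layout, np.random.default_rng(42))
        np.testing.assert_array_equal(a.zmat, b.zmat)

    def test_empty_column_rejected(self, mixed_specs):
        df = pd.DataFrame({"y": [np.nan, np.nan], "x1": [1.0, 2.0], "x2": [0.0, 1.0]})
        layout = build_latent_layout(mixed_specs)
        with pytest.raises(ValueError, match="'y'"):
            initialize(df, layout, np.random.default_rng(0))


class TestModel:
    def test_no_missing_data_returns_input_unchanged(self, mixed_specs, rng):
        df = gen_latent_matching(60, rng)
        res = LatentNormalModel(df, mixed_specs).fit(m=3, burnin=20, between=5, seed=1)
        assert res.m == 3
        for d in res.datasets:
            pd.testing.assert_frame_equal(d, df)

    def test_observed_cells_preserved_bit_exactly(self, mixed_incomplete, mixed_specs):
        _, dfm = mixed_incomplete
        res = LatentNormalModel(dfm, mixed_specs).fit(m=3, burnin=30, between=10, seed=2)
        obs = dfm.notna()
        for d in res.datasets:
            assert not d.isna().to_numpy().any()
            for col in dfm.columns:
                np.testing.assert_array_equal(
                    d.loc[obs[col], col].to_numpy(), dfm.loc[obs[col], col].to_numpy()
                )
            # imputed categorical/binary cells are valid level codes
            assert d["x1"].isin([1.0, 2.0, 3.0, 4.0]).all()
            assert d["x2"].isin([0.0, 1.0]).all()

    def test_fit_is_seed_deterministic(self, mixed_incomplete, mixed_specs):
        _, dfm = mixed_incomplete
        r1 = LatentNormalModel(dfm, mixed_specs).fit(m=2, burnin=25, between=5, seed=7)
        r2 = LatentNormalModel(dfm, mixed_specs).fit(m=2, burnin=25, between=5, seed=7)
        for a, b in zip(r1.datasets, r2.datasets):
            pd.testing.assert_frame_equal(a, b)

    def test_mcar_imputations_match_observed_marginal(self, rng):
        # under MCAR the imputed-value distribution should match the
        # observed one; check the continuous mean over pooled imputations
        df = gen_latent_matching(300, rng)
        dfm = df.copy()
        dfm.loc[rng.random(300) < 0.25, "y"] = np.nan
        specs = [
            VariableSpec("y", "continuous"),
            VariableSpec("x1", "categorical", n_levels=4),
            VariableSpec("x2", "binary"),
        ]
        res = LatentNormalModel(dfm, specs).fit(m=10, burnin=100, between=25, seed=3)
        miss = dfm["y"].isna()
        imputed = np.concatenate([d.loc[miss, "y"].to_numpy() for d in res.datasets])
        obs_mean = dfm["y"].mean()
        # draws are correlated across imputations; generous 4-sigma-ish band
        assert imputed.mean() == pytest.approx(obs_mean, abs=0.35)

    def test_missing_binary_with_symmetric_marginal(self, rng):
        n = 400
        x = rng.standard_normal(n)
        b = (rng.random(n) < 0.5).astype(float)
        dfm = pd.DataFrame({"x": x, "b": b})
        dfm.loc[rng.random(n) < 0.2, "b"] = np.nan
        specs = [VariableSpec("x", "continuous"), VariableSpec("b", "binary")]
        res = LatentNormalModel(dfm, specs).fit(m=10, burnin=100, between=25, seed=4)
        miss = dfm["b"].isna()
        freq = np.mean([d.loc[miss, "b"].mean() for d in res.datasets])
        assert freq == pytest.approx(0.5, abs=0.15)

    def test_count_imputations_nonnegative_unrounded(self, rng):
        n = 250
        x1 = rng.poisson(3, n).astype(float)
        y = 0.3 + 0.3 * x1 + rng.standard_normal(n)
        dfm = pd.DataFrame({"y": y, "x1": x1})
        dfm.loc[rng.random(n) < 0.3, "x1"] = np.nan
        specs = [VariableSpec("y", "continuous"), VariableSpec("x1", "count")]
        res = LatentNormalModel(dfm, specs).fit(m=5, burnin=80, between=20, seed=5)
        miss = dfm["x1"].isna()
        imput = np.concatenate([d.loc[miss, "x1"].to_numpy() for d in res.datasets])
        assert (imput >= 0).all()
        assert np.any(imput != np.round(imput))   # truncated, never rounded

    def test_count_as_categorical_imputes_observed_values(self, rng):
        n = 300
        x1 = rng.choice([0.0, 1.0, 2.0, 4.0], size=n, p=[0.4, 0.3, 0.2, 0.1])
        y = x1 + rng.standard_normal(n)
        dfm = pd.DataFrame({"y": y, "x1": x1})
        dfm.loc[rng.random(n) < 0.25, "x1"] = np.nan
        specs = [
            VariableSpec("y", "continuous"),
            VariableSpec("x1", "count", count_treatment="categorical"),
        ]
        model = LatentNormalModel(dfm, specs)
        assert model.layout.specs[1].kind == "categorical"
        res = model.fit(m=4, burnin=60, between=15, seed=6)
        miss = dfm["x1"].isna()
        for d in res.datasets:
            assert d.loc[miss, "x1"].isin([0.0, 1.0, 2.0, 4.0]).all()

    def test_log_offset_chosen_from_observed_zeros(self, rng):
        n = 200
        y = rng.poisson(0.7, n).astype(float)
        x = rng.standard_normal(n)
        dfm = pd.DataFrame({"y": y, "x": x})
        dfm.loc[rng.random(n) < 0.2, "y"] = np.nan
        specs = [VariableSpec("y", "count", count_treatment="log"),
                 VariableSpec("x", "continuous")]
        model = LatentNormalModel(dfm, specs)
        assert model._log_offsets["y"] == 1.0
        res = model.fit(m=2, burnin=40, between=10, seed=7)
        assert (res.datasets[0]["y"] >= 0).all()

    def test_invalid_inputs_rejected(self, rng):
        df = pd.DataFrame({"b": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="invalid observed"):
            LatentNormalModel(df, [VariableSpec("b", "binary")])
        df2 = pd.DataFrame({"c": [1.0, 5.0]})
        with pytest.raises(ValueError, match="invalid observed"):
            LatentNormalModel(df2, [VariableSpec("c", "categorical", n_levels=4)])
        df3 = pd.DataFrame({"y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="lacks declared"):
            LatentNormalModel(df3, [VariableSpec("z", "continuous")])
        with pytest.raises(ValueError, match="m must be"):
            LatentNormalModel(df3, [VariableSpec("y", "continuous")]).fit(m=0)

    def test_run_log_and_summary_report_diagnostics(self, mixed_incomplete, mixed_specs):
        _, dfm = mixed_incomplete
        res = LatentNormalModel(dfm, mixed_specs).fit(m=2, burnin=30, between=5, seed=8)
        log = res.run_log()
        assert log["n_imputations"] == 2
        assert all(0.0 <= r <= 1.0 for r in log["mh_acceptance"].values())
        assert log["rejection_cap_hits"] >= 0
        text = res.summary()
        assert "imputations: 2" in text and "x1" in text
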