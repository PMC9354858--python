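"""Linkage-density estimator: standardization, lagged OLS, SLD, reliability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sldnet
from sldnet.errors import DegenerateSeriesError, ReliabilityUndefinedError
from sldnet.scales import SYMPTOMS, SymptomSeries
from sldnet.sld import (
    SymptomLinkageModel,
    _fit_pairs_batched,
    compute_sld,
    cronbach_alpha,
    fit_lagged_pair,
    grand_moments,
    standardize_series,
)


def brute_force_sld(values, min_rows=4):
    """Independent normal-equations oracle: explicit inversion, plain loops."""
    Z = np.empty_like(values)
    for s in range(values.shape[1]):
        col = values[:, s]
        Z[:, s] = (col - col.mean()) / col.std(ddof=1)
    betas = []
    S = values.shape[1]
    for j in range(S):
        for k in range(S):
            if j == k:
                continue
            y = Z[1:, k]
            X = np.column_stack([np.ones(len(y)), Z[:-1, k], Z[:-1, j]])
            if len(y) < min_rows:
                continue
            b = np.linalg.inv(X.T @ X) @ (X.T @ y)
            betas.append(b[2])
    return np.mean(betas), len(betas)


class TestStandardize:
    def test_zscore_with_sample_sd(self):
        np.testing.assert_allclose(
            standardize_series(np.array([0.2, 0.4, 0.6])), [-1.0, 0.0, 1.0], atol=1e-12
        )

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            standardize_series(np.array([0.5, 0.5, 0.5]))

    def test_too_few_values_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            standardize_series(np.array([0.1, 0.9, np.nan, np.nan] + [np.nan] * 9))

    @given(
        st.floats(0.05, 5.0),
        st.floats(-2.0, 2.0),
        st.integers(0, 2**31 - 1),
    )
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).random(10)
        if np.std(x, ddof=1) == 0:
            return
        np.testing.assert_allclose(
            standardize_series(a * x + b), standardize_series(x), atol=1e-8
        )

    def test_missing_preserved(self):
        x = np.array([0.1, np.nan, 0.3, 0.5, np.nan])
        z = standardize_series(x)
        assert np.isnan(z[[1, 4]]).all()
        assert np.isfinite(z[[0, 2, 3]]).all()


class TestFitLaggedPair:
    k = np.array([0.0, 1.0, 0.0, -1.0, 0.5, -0.5, 1.0])
    j = np.array([1.0, 0.0, -1.0, 0.5, 0.0, 0.5, -1.0])

    def test_matches_normal_equations_oracle(self):
        # frozen from the explicit 3x3 inversion computed independently
        res = fit_lagged_pair(self.k, self.j)
        assert res.beta2 == pytest.approx(1.04743083, abs=1e-7)
        assert res.n_lag_rows == 6
        y, kl, jl = self.k[1:], self.k[:-1], self.j[:-1]
        X = np.column_stack([np.ones(6), kl, jl])
        oracle = np.linalg.inv(X.T @ X) @ (X.T @ y)
        assert res.beta2 == pytest.approx(oracle[2], abs=1e-12)
        assert res.beta1 == pytest.approx(oracle[1], abs=1e-12)
        assert res.beta0 == pytest.approx(oracle[0], abs=1e-12)

    def test_collinear_predictors_skipped(self):
        res = fit_lagged_pair(self.k, self.k.copy())
        assert res is None

    def test_too_few_rows_skipped(self):
        assert fit_lagged_pair(self.k[:4], self.j[:4], min_rows=4) is None
        assert fit_lagged_pair(self.k[:5], self.j[:5], min_rows=4) is not None

    def test_gaps_not_bridged(self):
        k = self.k.copy()
        j = self.j.copy()
        # knock out alternating weeks: no consecutive (t-1, t) pair remains
        k[::2] = np.nan
        j[::2] = np.nan
        assert fit_lagged_pair(k, j) is None

    def test_null_cross_lag_centered(self):
        """Monte-Carlo null: independent white-noise series give mean beta2 ~ 0."""
        rng = np.random.default_rng(123)
        betas = []
        for _ in range(4000):
            k = standardize_series(rng.normal(size=13))
            j = standardize_series(rng.normal(size=13))
            res = fit_lagged_pair(k, j)
            if res is not None:
                betas.append(res.beta2)
        betas = np.array(betas)
        se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean()) < 3 * se


class TestComputeSld:
    def test_sld_is_mean_of_retained_coefficients(self, complete_series):
        pl = compute_sld(complete_series)
        assert pl.sld == pytest.approx(np.mean([c.beta2 for c in pl.coefficients]))

    def test_full_data_retains_all_72_pairs(self, complete_series):
        pl = compute_sld(complete_series)
        assert pl.n_coefficients == 72
        assert all(c.n_lag_rows == 12 for c in pl.coefficients)

    def test_matches_brute_force_oracle(self, complete_series):
        pl = compute_sld(complete_series)
        oracle_sld, oracle_n = brute_force_sld(complete_series.values)
        assert pl.n_coefficients == oracle_n
        assert pl.sld == pytest.approx(oracle_sld, abs=1e-12)

    def test_batched_path_equals_per_pair_path(self, complete_series):
        Z = np.column_stack(
            [standardize_series(complete_series.values[:, s]) for s in range(9)]
        )
        batched = {
            (c.source, c.target): c for c in _fit_pairs_batched(Z, list(range(9)), SYMPTOMS, 4)
        }
        for j in range(9):
            for k in range(9):
                if j == k:
                    continue
                ref = fit_lagged_pair(Z[:, k], Z[:, j], source=SYMPTOMS[j], target=SYMPTOMS[k])
                got = batched[(SYMPTOMS[j], SYMPTOMS[k])]
                assert got.beta2 == pytest.approx(ref.beta2, abs=1e-10)
                assert got.se_beta2 == pytest.approx(ref.se_beta2, abs=1e-10)

    def test_ineligible_below_three_weeks(self):
        values = np.full((13, 9), np.nan)
        values[:2] = np.random.default_rng(0).random((2, 9))
        pl = compute_sld(SymptomSeries("p", values, observed_weeks=2))
        assert not pl.eligible and np.isnan(pl.sld) and pl.n_coefficients == 0

    def test_degenerate_symptom_drops_its_pairs(self, complete_series):
        values = complete_series.values.copy()
        values[:, 3] = 0.5  # one constant symptom
        pl = compute_sld(SymptomSeries("p", values, 13))
        assert pl.n_coefficients == 8 * 7  # eight usable symptoms
        names = {c.source for c in pl.coefficients} | {c.target for c in pl.coefficients}
        assert SYMPTOMS[3] not in names

    def test_below_min_coefficients_flagged_unreliable(self, complete_series):
        values = complete_series.values.copy()
        for s in (1, 3, 5):
            values[:, s] = 0.5
        pl = compute_sld(SymptomSeries("p", values, 13))  # 6*5 = 30 pairs < 48
        assert pl.n_coefficients == 30
        assert not pl.sld_reliable and np.isnan(pl.sld)
        pl2 = compute_sld(SymptomSeries("p", values, 13), min_coefficients=30)
        assert pl2.sld_reliable and np.isfinite(pl2.sld)

    def test_label_permutation_invariance(self, complete_series):
        pl = compute_sld(complete_series)
        perm = np.random.default_rng(3).permutation(9)
        permuted = SymptomSeries(
            "p", complete_series.values[:, perm], 13, symptoms=tuple(np.array(SYMPTOMS)[perm])
        )
        assert compute_sld(permuted).sld == pytest.approx(pl.sld, abs=1e-12)

    def test_affine_rescaling_invariance(self, complete_series):
        pl = compute_sld(complete_series)
        scaled = SymptomSeries("p", complete_series.values * 0.5 + 0.2, 13)
        assert compute_sld(scaled).sld == pytest.approx(pl.sld, abs=1e-9)

    def test_consecutive_weeks_required(self):
        rng = np.random.default_rng(5)
        values = rng.random((13, 9))
        values[1::2] = np.nan  # weeks 2, 4, ... missing: no usable lag row
        pl = compute_sld(SymptomSeries("p", values, observed_weeks=7))
        assert pl.n_coefficients == 0


class TestGrandMoments:
    def test_constant(self):
        m, s = grand_moments(np.full((13, 9), 0.3))
        assert (m, s) == (pytest.approx(0.3), pytest.approx(0.0))

    def test_balanced_zero_one(self):
        v = np.zeros((2, 9))
        v[1] = 1.0
        m, s = grand_moments(v)
        assert m == pytest.approx(0.5)
        assert s == pytest.approx(np.std(v.ravel(), ddof=1))

    def test_pooled_over_nonmissing(self):
        v = np.full((13, 9), np.nan)
        v[0, :3] = [0.1, 0.2, 0.6]
        m, s = grand_moments(v)
        assert m == pytest.approx(0.3)
        assert s == pytest.approx(np.std([0.1, 0.2, 0.6], ddof=1))

    def test_single_value_undefined_sd(self):
        v = np.full((13, 9), np.nan)
        v[0, 0] = 0.4
        m, s = grand_moments(v)
        assert m == pytest.approx(0.4) and np.isnan(s)


class TestCronbachAlpha:
    def test_identical_columns_unity(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=40)
        wide = pd.DataFrame({f"c{i}": col for i in range(72)})
        assert cronbach_alpha(wide) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        wide = pd.DataFrame(rng.normal(size=(3000, 20)))
        assert abs(cronbach_alpha(wide)) < 0.1

    def test_insufficient_data_undefined(self):
        with pytest.raises(ReliabilityUndefinedError):
            cronbach_alpha(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))

    def test_strong_density_factor_gives_high_alpha(self):
        """With a wide patient density spread and complete data, the 72
        cross-lag coefficients behave as parallel indicators of one patient
        factor (alpha computed 0.92 under this configuration)."""
        from sldnet.simulate import generate_cohort, primary_like

        cfg = primary_like(
            n_patients=300, seed=17, density_sd=0.6, trend_change=0.0,
            trend_change_sd=0.0, symptom_trend_sd=0.0, missing_week_rate=0.0,
        )
        cohort = generate_cohort(cfg, item_level=False)
        res = SymptomLinkageModel(cohort.series_long).fit()
        assert res.alpha >= 0.9


class TestModelResults:
    def test_patient_table_and_coefficients_align(self, small_cohort):
        res = SymptomLinkageModel.from_items(small_cohort.items).fit()
        tab = res.patient_table
        coef = res.coefficients
        counts = coef.groupby("patient_id").size()
        for _, row in tab.iterrows():
            assert counts.get(row["patient_id"], 0) == row["n_coefficients"]
        assert tab["n_coefficients"].between(0, 72).all()

    def test_edge_matrix_shape_and_mean(self, small_cohort):
        res = SymptomLinkageModel.from_items(small_cohort.items).fit()
        mat = res.edge_matrix()
        assert mat.shape == (9, 9)
        assert np.isnan(np.diag(mat)).all()
        coef = res.coefficients
        j, k = coef["j"].iloc[0], coef["k"].iloc[0]
        manual = coef[(coef["j"] == j) & (coef["k"] == k)]["beta2"].mean()
        assert mat.loc[j, k] == pytest.approx(manual)

    def test_shrinkage_reduces_dispersion(self, small_cohort):
        plain = SymptomLinkageModel.from_items(small_cohort.items).fit()
        shrunk = SymptomLinkageModel.from_items(small_cohort.items, shrinkage=True).fit()
        sd_plain = plain.patient_table["sld"].std(ddof=1)
        sd_shrunk = shrunk.patient_table["sld"].std(ddof=1)
        assert sd_shrunk <= sd_plain

    def test_summary_mentions_key_quantities(self, small_cohort):
        res = SymptomLinkageModel.from_items(small_cohort.items).fit()
        text = res.summary()
        assert "SLD" in text and "eligible" in text
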