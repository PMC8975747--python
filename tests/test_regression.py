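"""Temperature x chlorophyll regression: fitting, selection, intervals, and
masked gridded prediction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cyanotransect import schema
from cyanotransect.regression import (
    CANDIDATE_SETS,
    RegressionModel,
    fit_model,
    grid_predict,
    predict_with_interval,
    rmse,
    train_test_evaluate,
)
from cyanotransect.synthetic import simulate_regression_dataset

COEFFS = (4.0, 0.08, -2.0, 0.1)


class TestRmse:
    def test_perfect_prediction(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_closed_form(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(25 / 2))

    def test_permutation_invariance(self, rng):
        p = rng.normal(size=20)
        o = rng.normal(size=20)
        perm = rng.permutation(20)
        assert rmse(p, o) == pytest.approx(rmse(p[perm], o[perm]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])


class TestFitModel:
    def test_noise_free_recovery_to_six_digits(self):
        df = simulate_regression_dataset(COEFFS, 200, 0.0, seed=0)
        m = fit_model(df)
        np.testing.assert_allclose(m.coefficients, COEFFS, rtol=1e-6)
        assert m.rmse_train < 1e-10

    def test_single_seed_estimates_within_three_se(self):
        df = simulate_regression_dataset(COEFFS, 87, 0.15, seed=1)
        m = fit_model(df)
        assert (np.abs(m.coefficients - np.asarray(COEFFS)) <= 3 * m.standard_errors()).all()

    def test_duplicate_design_equals_weighted_fit(self):
        df = simulate_regression_dataset(COEFFS, 40, 0.1, seed=2)
        doubled = pd.concat([df, df], ignore_index=True)
        m_dup = fit_model(doubled)
        X = m_dup.design(df)
        y = np.log10(df[schema.PHAGE_TOTAL])
        wls = sm.WLS(y, X, weights=2.0).fit()
        np.testing.assert_allclose(m_dup.coefficients, wls.params, rtol=1e-10)

    def test_residuals_orthogonal_to_design(self):
        df = simulate_regression_dataset(COEFFS, 100, 0.2, seed=3)
        m = fit_model(df)
        X = m.design(df)
        resid = np.log10(df[schema.PHAGE_TOTAL]) - m.predict_response(df)
        np.testing.assert_allclose(X.T @ resid, 0.0, atol=1e-8)

    def test_rank_deficient_design_names_column(self):
        df = simulate_regression_dataset(COEFFS, 50, 0.1, seed=4)
        df[schema.CHL] = 0.3  # constant -> Chl and T x Chl collinear with T
        with pytest.raises(ValueError, match="collinear"):
            fit_model(df)

    def test_too_few_samples_rejected(self):
        df = simulate_regression_dataset(COEFFS, 7, 0.1, seed=5)
        with pytest.raises(ValueError):
            fit_model(df)

    def test_json_round_trip(self, tmp_path):
        df = simulate_regression_dataset(COEFFS, 60, 0.1, seed=6)
        m = fit_model(df)
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = RegressionModel.from_json(path)
        np.testing.assert_allclose(m.coefficients, m2.coefficients)
        assert m.features == m2.features


class TestTrainTestEvaluate:
    def test_identity_split_equalizes_rmse(self):
        df = simulate_regression_dataset(COEFFS, 80, 0.1, seed=7)
        rank = train_test_evaluate(df, df, {"T+Chl+TxChl": CANDIDATE_SETS["T+Chl+TxChl"]})
        row = rank.iloc[0]
        assert row["rmse_test"] == pytest.approx(row["rmse_train"])

    def test_missing_candidate_columns_skipped_with_warning(self):
        df = simulate_regression_dataset(COEFFS, 80, 0.1, seed=8)
        with pytest.warns(UserWarning, match="skipped"):
            rank = train_test_evaluate(df, df)
        assert "T+logPro+TxlogPro" not in set(rank["candidate"])
        assert "T+Chl+TxChl" in set(rank["candidate"])

    def test_irrelevant_predictor_leaves_true_model_rmse_unchanged(self, rng):
        tr = simulate_regression_dataset(COEFFS, 80, 0.1, seed=9)
        te = simulate_regression_dataset(COEFFS, 80, 0.1, seed=10)
        tr["noise_col"] = rng.normal(size=len(tr))
        te["noise_col"] = rng.normal(size=len(te))
        cands = {
            "true": CANDIDATE_SETS["T+Chl+TxChl"],
            "true+noise": CANDIDATE_SETS["T+Chl+TxChl"] + ("noise_col",),
        }
        rank = train_test_evaluate(tr, te, cands)
        true_rmse = rank.set_index("candidate").loc["true", "rmse_test"]
        base = train_test_evaluate(tr, te, {"true": CANDIDATE_SETS["T+Chl+TxChl"]})
        assert true_rmse == pytest.approx(base["rmse_test"].iloc[0])

    def test_deployment_default_tagged(self):
        df = simulate_regression_dataset(COEFFS, 80, 0.1, seed=11)
        rank = train_test_evaluate(df, df, {k: CANDIDATE_SETS[k] for k in ("T+Chl+TxChl", "T")})
        tagged = rank[rank["deployment_default"]]
        assert list(tagged["candidate"]) == ["T+Chl+TxChl"]


class TestPredictWithInterval:
    def test_zero_noise_interval_collapses_on_truth(self):
        df = simulate_regression_dataset(COEFFS, 200, 0.0, seed=12)
        m = fit_model(df)
        k0, k1, k2, k3 = COEFFS
        pt, lo, hi, masked = predict_with_interval(m, 15.0, 0.2)
        truth = 10 ** (k0 + k1 * 15 + k2 * 0.2 + k3 * 15 * 0.2)
        assert not masked
        assert pt == pytest.approx(truth, rel=1e-6)
        assert hi - lo < 1e-4 * pt

    def test_ordering_and_asymmetry_on_natural_scale(self):
        df = simulate_regression_dataset(COEFFS, 87, 0.2, seed=13)
        m = fit_model(df)
        pt, lo, hi, _ = predict_with_interval(m, 15.0, 0.2)
        assert lo < pt < hi
        assert (hi - pt) > (pt - lo)  # lognormal back-transform is right-skewed

    def test_interval_narrowest_near_training_centroid(self):
        df = simulate_regression_dataset(COEFFS, 500, 0.1, seed=14)
        m = fit_model(df)
        tgrid = np.linspace(10, 24, 40)
        chl = float(df[schema.CHL].mean())
        _, lo, hi, _ = predict_with_interval(m, tgrid, np.full_like(tgrid, chl),
                                             kind="mean", apply_mask=False)
        width = np.log10(hi) - np.log10(lo)
        t_narrow = tgrid[np.argmin(width)]
        assert abs(t_narrow - df[schema.TEMP].mean()) < 2.0

    def test_masked_outside_validity_domain(self):
        df = simulate_regression_dataset(COEFFS, 87, 0.1, seed=15)
        m = fit_model(df)
        pt, lo, hi, masked = predict_with_interval(m, 4.0, 0.2)
        assert masked and np.isnan(pt)
        pt, _, _, masked = predict_with_interval(m, 15.0, 0.5)
        assert masked and np.isnan(pt)


class TestGridPredict:
    def test_mask_and_noise_free_surface_identity(self):
        df = simulate_regression_dataset(COEFFS, 200, 0.0, seed=16)
        m = fit_model(df)
        T = np.array([[4.0, 15.0], [20.0, 10.0]])
        C = np.array([[0.2, 0.5], [0.1, np.nan]])
        grid = grid_predict({"total": m}, T, C)
        assert not grid.valid[0, 0]     # too cold
        assert not grid.valid[0, 1]     # chlorophyll above mask
        assert not grid.valid[1, 1]     # missing input propagates
        assert grid.valid[1, 0]
        k0, k1, k2, k3 = COEFFS
        truth = 10 ** (k0 + k1 * 20 + k2 * 0.1 + k3 * 20 * 0.1)
        assert grid.predicted["total"][1, 0] == pytest.approx(truth, rel=1e-6)
        assert np.isnan(grid.predicted["total"][0, 0])

    def test_lineage_ratio_computed_where_both_valid(self):
        df = simulate_regression_dataset(COEFFS, 200, 0.0, seed=17)
        m = fit_model(df)
        grid = grid_predict({"t4": m, "t7b": m}, np.array([[15.0]]), np.array([[0.2]]))
        assert grid.ratio_t4_t7b[0, 0] == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        df = simulate_regression_dataset(COEFFS, 200, 0.0, seed=18)
        m = fit_model(df)
        with pytest.raises(ValueError, match="shape"):
            grid_predict({"total": m}, np.zeros((2, 2)), np.zeros((3, 2)))
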