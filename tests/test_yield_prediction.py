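"""Correlation screen, LOOCV scoring conventions, and Shapley attribution."""

import numpy as np
import pandas as pd
import pytest

from panicov import synthetic_data as sd
from panicov import yield_prediction as yp


@pytest.fixture(scope="module")
def small_table():
    params = sd.sample_params_envelope(60, seed=1)
    return sd.generate_yield_table(params, seed=2)


class TestCorrelationScreen:
    def test_feature_duplicated_as_target_has_unit_correlation(self, small_table):
        t = small_table.copy()
        t["Yield"] = t["K"]
        r, p, stars = yp.correlation_screen(t)
        assert r.loc["K", "Yield"] == pytest.approx(1.0)
        assert stars.loc["K", "Yield"] == "***"

    def test_sign_pattern_on_default_table(self, yield_table_200):
        r, _, _ = yp.correlation_screen(yield_table_200)
        assert r.loc["K", "Yield"] > 0
        assert r.loc["d0", "FGR"] < 0

    def test_independent_noise_mostly_uncorrelated(self):
        rng = np.random.default_rng(0)
        cols = [*yp.FEATURES, *yp.TARGETS]
        t = pd.DataFrame(rng.normal(size=(200, len(cols))), columns=cols)
        r, _, _ = yp.correlation_screen(t)
        # |r| < 0.2 for ~95% of pairs at n=200 under the null
        assert (r.abs() < 0.2).to_numpy().mean() > 0.9

    def test_zero_variance_column_flagged(self, small_table):
        t = small_table.copy()
        t["TGW"] = 5.0
        r, p, stars = yp.correlation_screen(t)
        assert np.isnan(r.loc["K", "TGW"])
        assert stars.loc["K", "TGW"] == "!"


class TestScores:
    def test_rmse_identical_vectors_is_zero(self):
        assert yp.rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_rmse_hand_example(self):
        assert yp.rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_rmse_homogeneous_in_scale(self, rng):
        a, p = rng.normal(size=30), rng.normal(size=30)
        assert yp.rmse(3 * a, 3 * p) == pytest.approx(3 * yp.rmse(a, p))

    def test_rmse_literal_half_convention(self):
        # the sum-over-two form: sqrt(sum/2) instead of sqrt(mean)
        assert yp.rmse([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], literal_half=True) == (
            pytest.approx(np.sqrt(3 / 2))
        )

    def test_r_squared_perfect_and_mean_predictor(self, rng):
        y = rng.normal(size=20)
        assert yp.r_squared(y, y) == 1.0
        assert yp.r_squared(y, np.full(20, y.mean())) == pytest.approx(0.0)

    def test_r_squared_four_point_hand_example(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([1.5, 2.0, 2.5, 4.0])
        # SSres = 0.25 + 0 + 0.25 + 0 = 0.5; SStot = 5.0
        assert yp.r_squared(y, pred) == pytest.approx(1 - 0.5 / 5.0)

    def test_r_squared_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            yp.r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_pooled_consistency_identity(self, rng):
        # R^2 = 1 - n*RMSE^2 / SStot on the same pooled predictions
        y = rng.normal(size=40)
        pred = y + rng.normal(scale=0.3, size=40)
        sstot = np.sum((y - y.mean()) ** 2)
        assert yp.r_squared(y, pred) == pytest.approx(
            1 - 40 * yp.rmse(y, pred) ** 2 / sstot
        )


class TestLoocv:
    def test_exact_linear_function_recovered_by_pls(self, small_table):
        t = small_table.copy()
        t["Yield"] = 100.0 + 12.0 * t["K"]
        res = yp.loocv(t, "plsr", "Yield", seed=0)
        assert res.r_squared > 0.99

    def test_each_record_predicted_exactly_once(self, small_table):
        res = yp.loocv(small_table, "rfr", "Yield", seed=0)
        assert res.predicted.shape == (len(small_table),)
        assert np.all(np.isfinite(res.predicted))

    def test_pure_noise_target_has_no_skill(self, small_table):
        t = small_table.copy()
        rng = np.random.default_rng(3)
        t["Yield"] = rng.normal(size=len(t))
        for model in ("plsr", "rfr"):
            res = yp.loocv(t, model, "Yield", seed=0)
            assert res.r_squared <= 0.1

    def test_unknown_model_rejected(self, small_table):
        with pytest.raises(ValueError):
            yp.loocv(small_table, "svr", "Yield")

    def test_deterministic_given_seed(self, small_table):
        a = yp.loocv(small_table, "xgbr", "Yield", seed=5)
        b = yp.loocv(small_table, "xgbr", "Yield", seed=5)
        assert np.array_equal(a.predicted, b.predicted)


@pytest.fixture(scope="module")
def fitted_rf(yield_table_200):
    t = yield_table_200.iloc[:80]
    model = yp.make_model("rfr", seed=0)
    model.fit(t[list(yp.FEATURES)].to_numpy(), t["Yield"].to_numpy())
    return model, t


class TestAttribution:
    def test_additivity_holds_for_every_record(self, fitted_rf):
        model, t = fitted_rf
        rep = yp.attribute(model, t, background=t.iloc[:30])
        recon = rep.base_value + rep.contributions.sum(axis=1)
        scale = np.ptp(rep.predictions)
        assert np.abs(recon - rep.predictions).max() < 1e-6 * scale

    def test_single_feature_dependence_ranks_that_feature_first(self, small_table):
        t = small_table.copy()
        t["Yield"] = 50.0 * t["K"]
        model = yp.make_model("rfr", seed=0)
        model.fit(t[list(yp.FEATURES)].to_numpy(), t["Yield"].to_numpy())
        rep = yp.attribute(model, t, background=t.iloc[:20])
        assert rep.ranking().index[0] == "K"

    def test_constant_model_attributes_nothing(self, small_table):
        t = small_table.copy()
        t["Yield"] = 7.0
        model = yp.make_model("rfr", seed=0)
        model.fit(t[list(yp.FEATURES)].to_numpy(), t["Yield"].to_numpy())
        rep = yp.attribute(model, t.iloc[:10], background=t.iloc[:10])
        assert np.abs(rep.contributions).max() < 1e-9

    def test_agrees_with_xgboost_builtin_tree_shap_on_additivity(self, small_table):
        # independent route: xgboost's native per-feature contributions
        import xgboost as xgb

        t = small_table
        X = t[list(yp.FEATURES)].to_numpy()
        model = yp.make_model("xgbr", seed=0)
        model.fit(X, t["Yield"].to_numpy())
        rep = yp.attribute(model, t, background=t)
        contrib = model.get_booster().predict(xgb.DMatrix(X), pred_contribs=True)
        # both decompositions must reconstruct the same predictions
        theirs = contrib.sum(axis=1)
        ours = rep.base_value + rep.contributions.sum(axis=1)
        assert ours == pytest.approx(theirs, rel=1e-4)
        # and agree on the dominant feature
        xgb_rank = np.argsort(-np.abs(contrib[:, :-1]).mean(axis=0))
        assert rep.ranking().index[0] == yp.FEATURES[xgb_rank[0]]

    def test_non_tree_model_rejected_with_linear_fallback(self, small_table):
        t = small_table
        pls = yp.make_model("plsr", seed=0)
        pls.fit(t[list(yp.FEATURES)].to_numpy(), t["Yield"].to_numpy())
        with pytest.raises(yp.UnsupportedModelError):
            yp.attribute(pls, t)
        rep = yp.linear_attribution(pls, t)
        recon = rep.base_value + rep.contributions.sum(axis=1)
        assert recon == pytest.approx(rep.predictions, rel=1e-9)


class TestReportTable:
    def test_single_result_single_cell(self, small_table):
        res = yp.loocv(small_table, "plsr", "Yield", seed=0)
        table = yp.report_table([res])
        assert table.loc[("Yield", "R2"), "plsr"] == pytest.approx(res.r_squared)

    def test_grid_shape_is_targets_by_metrics_by_models(self, small_table):
        results = []
        for m in ("plsr", "rfr"):
            for tgt in ("Yield", "TGW"):
                results.append(yp.loocv(small_table, m, tgt, seed=0))
        table = yp.report_table(results)
        assert table.shape == (4, 2)  # 2 targets x 2 metrics rows, 2 model cols
        assert table.notna().all().all()

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            yp.report_table([])
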