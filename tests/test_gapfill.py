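"""Splitting, normalization, model training/evaluation, CV, tuning,
gap prediction and plausibility checks."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import KFold

import dendrogap as dg
from dendrogap.errors import DendrogapError
from dendrogap.gapfill import FitResult, fit_normalizer, train_model

from conftest import make_growth


def _xy(n=2000, seed=0, noise=0.0):
    """Smooth seasonal label on a calendar grid crossing year boundaries
    (so every temporal feature varies)."""
    idx = pd.date_range("2020-12-28", periods=n, freq="12h")
    X = pd.DataFrame(
        {
            "DOY": idx.dayofyear.astype(int),
            "year": idx.year.astype(int),
            "hour": (idx.hour + idx.minute / 60.0).astype(float),
        }
    )
    rng = np.random.default_rng(seed)
    y = 500.0 / (1 + np.exp(-0.1 * (X["DOY"] + X["hour"] / 24 - 40)))
    return X, pd.Series(y + rng.normal(0, noise, n), name="y")


class TestStratifiedSplit:
    def test_exact_division_in_even_strata(self):
        X = pd.DataFrame({"year": np.repeat([2019, 2020, 2021, 2022, 2023], 20),
                          "hour": 0.0})
        y = pd.Series(np.zeros(100))
        tr, te = dg.stratified_split(X, y, seed=0)
        assert len(tr) == 80 and len(te) == 20
        for yr in X["year"].unique():
            assert (X["year"].iloc[tr] == yr).sum() == 16
            assert (X["year"].iloc[te] == yr).sum() == 4

    def test_disjoint_and_exhaustive(self):
        X, y = _xy(500)
        tr, te = dg.stratified_split(X, y, seed=1)
        assert len(set(tr) & set(te)) == 0
        assert len(tr) + len(te) == 500

    def test_same_seed_identical(self):
        X, y = _xy(500)
        a = dg.stratified_split(X, y, seed=5)
        b = dg.stratified_split(X, y, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_overall_fraction_near_eighty_percent(self):
        X, y = _xy(3000, seed=2)
        tr, te = dg.stratified_split(X, y, seed=2)
        n_strata = X.groupby(["year", "hour"]).ngroups
        assert abs(len(tr) - 0.8 * len(X)) <= n_strata  # within 1 row per stratum

    def test_singleton_stratum_goes_to_train_with_warning(self):
        X = pd.DataFrame({"year": [2020, 2020, 2020, 2021], "hour": [0.0, 0.0, 0.0, 5.0]})
        y = pd.Series([1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="size 1"):
            tr, te = dg.stratified_split(X, y, seed=0)
        assert 3 in tr


class TestNormalizer:
    def test_transform_centres_and_scales(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        params = dg.fit_normalizer(X)
        Z = dg.apply_normalizer(X, params)
        assert Z["a"].mean() == pytest.approx(0.0, abs=1e-10)
        assert Z["a"].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_train_params_applied_to_shifted_target_rows(self):
        train = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        test = pd.DataFrame({"a": [10.0, 11.0, 12.0]})
        params = dg.fit_normalizer(train)
        Z = dg.apply_normalizer(test, params)
        assert Z["a"].mean() > 5  # shift preserved in transformed space

    def test_zero_variance_column_named_in_error(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(DendrogapError, match="'flat'"):
            dg.fit_normalizer(X)


class TestTrainAndEvaluate:
    def test_smooth_function_fit_is_nearly_exact(self):
        X, y = _xy(4000)
        norm = dg.fit_normalizer(X)
        fit = dg.train_model(dg.apply_normalizer(X, norm), y, seed=0, norm=norm)
        assert fit.rmse_train < 0.01 * (y.max() - y.min())

    def test_nonlinear_label_favors_boosting_over_ridge(self):
        X, y = _xy(4000, noise=1.0)
        tr, te = dg.stratified_split(X, y, seed=0)
        norm = dg.fit_normalizer(X.iloc[tr])
        Ztr, Zte = dg.apply_normalizer(X.iloc[tr], norm), dg.apply_normalizer(X.iloc[te], norm)
        rmse_x, _ = dg.evaluate(dg.train_model(Ztr, y.iloc[tr], "xgb", seed=0), Zte, y.iloc[te])
        rmse_r, _ = dg.evaluate(dg.train_model(Ztr, y.iloc[tr], "ridge", seed=0), Zte, y.iloc[te])
        assert rmse_x < rmse_r

    def test_same_seed_identical_metrics(self):
        X, y = _xy(2000, noise=2.0)
        norm = dg.fit_normalizer(X)
        Z = dg.apply_normalizer(X, norm)
        a = dg.train_model(Z, y, seed=9)
        b = dg.train_model(Z, y, seed=9)
        assert a.rmse_train == b.rmse_train and a.adj_r2_train == b.adj_r2_train

    def test_unknown_algorithm_rejected(self):
        X, y = _xy(100)
        with pytest.raises(DendrogapError, match="unknown algorithm"):
            dg.train_model(X, y, algorithm="nope")

    def test_perfect_predictions_score_perfectly(self):
        fit = _stub_fit(["x"], np.array([1.0, 2.0, 3.0, 4.0]))
        rmse, ar2 = dg.evaluate(fit, pd.DataFrame({"x": np.zeros(4)}), pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert rmse == 0.0 and ar2 == pytest.approx(1.0)

    def test_mean_prediction_gives_negative_adjusted_r2(self):
        y = pd.Series([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = _stub_fit(["x"], np.full(5, y.mean()))
        rmse, ar2 = dg.evaluate(fit, pd.DataFrame({"x": np.zeros(5)}), y)
        n, p = 5, 1
        assert ar2 == pytest.approx(1 - (n - 1) / (n - p - 1))
        assert ar2 < 0

    def test_hand_computed_rmse_and_adjusted_r2(self):
        y = pd.Series([0.0, 1.0, 2.0, 3.0, 4.0])
        yhat = np.array([0.0, 1.0, 2.0, 3.0, 5.0])
        fit = _stub_fit(["x"], yhat)
        rmse, ar2 = dg.evaluate(fit, pd.DataFrame({"x": np.zeros(5)}), y)
        assert rmse == pytest.approx(np.sqrt(1 / 5))
        r2 = 1 - 1.0 / 10.0
        assert ar2 == pytest.approx(1 - (1 - r2) * 4 / 3)


class _StubModel:
    def __init__(self, out):
        self.out = np.asarray(out, dtype=float)

    def predict(self, X):
        return self.out[: len(X)]


def _stub_fit(names, predictions):
    return FitResult(
        algorithm="stub", model=_StubModel(predictions), norm=None,
        feature_names=list(names),
        feature_ranges=pd.DataFrame({"min": [0.0], "max": [1.0]}, index=names),
        rmse_train=0.0, adj_r2_train=1.0, n_train=10, p=len(names), seed=0,
    )


class TestCrossValidate:
    def test_row_count_is_k_times_repeats(self):
        X, y = _xy(200, noise=1.0)
        table = dg.cross_validate(X, y, algorithm="ridge", k=10, repeats=10, seed=0)
        assert len(table) == 100

    def test_leave_one_out_row_count(self):
        X, y = _xy(30, noise=1.0)
        table = dg.cross_validate(X, y, algorithm="ridge", k=30, repeats=1, seed=0)
        assert len(table) == 30

    def test_same_seed_identical_table(self):
        X, y = _xy(200, noise=1.0)
        a = dg.cross_validate(X, y, algorithm="ridge", k=5, repeats=2, seed=4)
        b = dg.cross_validate(X, y, algorithm="ridge", k=5, repeats=2, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_k_below_two_rejected(self):
        X, y = _xy(50)
        with pytest.raises(DendrogapError):
            dg.cross_validate(X, y, k=1)


class TestTuneModel:
    def test_tuned_never_worse_than_defaults_on_same_folds(self):
        X, y = _xy(300, noise=5.0)
        fit = dg.tune_model(X, y, algorithm="ridge", iterations=3, k=3, seed=0)
        # default-configuration CV RMSE on the identical folds
        folds = KFold(n_splits=3, shuffle=True, random_state=0).split(X)
        vals = []
        for tr, te in folds:
            norm = dg.fit_normalizer(X.iloc[tr])
            f = dg.train_model(dg.apply_normalizer(X.iloc[tr], norm), y.iloc[tr],
                               algorithm="ridge", seed=0, norm=norm)
            yhat = f.model.predict(dg.apply_normalizer(X.iloc[te], norm).values)
            vals.append(np.sqrt(np.mean((y.iloc[te].values - yhat) ** 2)))
        assert fit.cv_rmse <= np.mean(vals) + 1e-9

    def test_same_seed_same_choice(self):
        X, y = _xy(200, noise=5.0)
        a = dg.tune_model(X, y, algorithm="ridge", iterations=2, k=3, seed=7)
        b = dg.tune_model(X, y, algorithm="ridge", iterations=2, k=3, seed=7)
        assert a.best_params == b.best_params

    def test_single_iteration_runs(self):
        X, y = _xy(100, noise=5.0)
        fit = dg.tune_model(X, y, algorithm="knn", iterations=1, k=3, seed=1)
        assert fit.cv_rmse is not None

    def test_zero_iterations_rejected(self):
        X, y = _xy(100)
        with pytest.raises(DendrogapError):
            dg.tune_model(X, y, iterations=0)


class TestPredictGaps:
    def test_empty_gap_set(self):
        fit = _stub_fit(["x"], [])
        out = dg.predict_gaps(fit, pd.DataFrame({"x": []}))
        assert len(out) == 0

    def test_all_gap_rows_predicted_and_flagged(self):
        fit = _stub_fit(["x"], [1.0, 2.0, 3.0])
        out = dg.predict_gaps(fit, pd.DataFrame({"x": [0.1, 0.5, 0.9]}))
        assert out["G_pred"].notna().all()
        assert (out["source_flag"] == "ml_fill").all()
        assert not out["extrapolated"].any()

    def test_out_of_range_rows_flagged_extrapolated(self):
        fit = _stub_fit(["x"], [1.0, 2.0])
        out = dg.predict_gaps(fit, pd.DataFrame({"x": [0.5, 7.0]}))
        assert out["extrapolated"].tolist() == [False, True]


class TestSanityCheck:
    def _series(self, values, start="2020-06-01"):
        idx = pd.date_range(start, periods=len(values), freq="30min")
        return pd.Series(values, index=idx)

    def test_monotone_continuous_fill_is_clean(self):
        s = self._series(np.linspace(10, 20, 200))
        assert dg.sanity_check(s, flank_before=10.0, flank_after=20.0) == []

    def test_multiday_decline_warned(self):
        up = np.linspace(0, 50, 48)
        down = np.linspace(50, 30, 160)  # > 3 days of decline
        s = self._series(np.concatenate([up, down]))
        warnings_ = dg.sanity_check(s)
        assert any("decreasing" in w for w in warnings_)

    def test_negative_values_warned(self):
        s = self._series([1.0, -5.0, 2.0])
        assert any("negative" in w for w in dg.sanity_check(s))

    def test_flank_discontinuity_warned(self):
        s = self._series(np.linspace(100, 120, 50))
        out = dg.sanity_check(s, flank_before=10.0, discontinuity_um=50.0)
        assert any("preceding" in w for w in out)


class TestLeakage:
    def test_normalization_depends_only_on_training_rows(self):
        X, y = _xy(1000, noise=1.0)
        tr, te = dg.stratified_split(X, y, seed=0)
        norm = dg.fit_normalizer(X.iloc[tr])
        # recompute from scratch on the training rows alone
        assert np.allclose(norm.mean.values, X.iloc[tr].mean().values)
        assert np.allclose(norm.sd.values, X.iloc[tr].std(ddof=0).values)
        # perturbing test rows cannot change the parameters
        X2 = X.copy()
        X2.iloc[te] += 1000.0
        norm2 = dg.fit_normalizer(X2.iloc[tr])
        assert np.array_equal(norm.mean.values, norm2.mean.values)
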