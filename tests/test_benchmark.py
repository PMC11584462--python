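"""Benchmark harness, permutation importance and nonparametric tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.special
import scipy.stats

import dendrogap as dg
from dendrogap.benchmark import BenchmarkDataset, GapWindow
from dendrogap.errors import DendrogapError

from conftest import make_growth


class TestGapWindows:
    def test_five_years_give_fifteen_windows(self):
        wins = dg.make_artificial_gaps(range(2019, 2024))
        assert len(wins) == 15

    def test_one_year_gives_three(self):
        assert len(dg.make_artificial_gaps([2020])) == 3

    def test_start_window_spans_1440_half_hour_slots(self):
        w = GapWindow("start", 2020)
        idx = pd.date_range("2020-01-01", "2020-12-31 23:30", freq="30min")
        assert w.mask(idx).sum() == 30 * 48
        assert w.first_day == pd.Timestamp("2020-04-16")
        assert w.last_day == pd.Timestamp("2020-05-15")

    def test_fixed_period_dates(self):
        assert GapWindow("middle", 2021).first_day == pd.Timestamp("2021-06-01")
        assert GapWindow("end", 2021).last_day == pd.Timestamp("2021-09-30")


def _sim_growths(n=2, rho=0.9, seed=13):
    p = dg.SimParams(years=(2020,), noise_sd=1.0, seed=seed)
    bundles = dg.simulate_network(n, rho, p)
    return [dg.zero_growth(b[0]) for b in bundles]


class TestRunBenchmark:
    def test_row_count_and_oracle_method(self):
        growths = _sim_growths(1)
        ds = BenchmarkDataset("t", growths)
        truth = {g.tree_id: g.frame["G"] for g in growths}

        def oracle(blanked, window):
            return {tid: s for tid, s in truth.items()}

        def mean_filler(blanked, window):
            return {
                t.tree_id: pd.Series(
                    np.nanmean(t.frame["G"].values), index=t.frame.index
                )
                for t in blanked
            }

        res = dg.run_benchmark(
            [ds],
            methods=[("oracle", oracle), ("mean", mean_filler)],
            windows=dg.make_artificial_gaps([2020]),
        )
        assert len(res.table) == 6  # 1 dataset × 3 windows × 2 methods
        assert res.n_ml_fits == 0
        orc = res.table[res.table.method == "oracle"]
        assert (orc.rmse.values == 0).all()
        assert (res.table[res.table.method == "mean"].rmse.values > 0).all()

    def test_window_outside_span_marked_not_applicable(self):
        growths = _sim_growths(1)
        ds = BenchmarkDataset("t", growths)
        res = dg.run_benchmark(
            [ds], methods=["spline"], windows=dg.make_artificial_gaps([1999])
        )
        assert not res.table.applicable.any()

    def test_ml_method_counts_fits_and_never_sees_truth(self):
        captured = {}

        class Probe:
            def __init__(self):
                self.n = None

            def fit(self, X, y, **kw):
                captured["n"] = len(X)
                captured["y"] = np.asarray(y)
                self._mean = float(np.mean(y))
                return self

            def predict(self, X):
                return np.full(len(X), self._mean)

        dg.register_algorithm("probe", lambda seed, **kw: Probe())
        try:
            growths = _sim_growths(1)
            ds = BenchmarkDataset("t", growths)
            w = GapWindow("middle", 2020)
            res = dg.run_benchmark([ds], methods=["probe"], windows=[w])
            assert res.n_ml_fits == 1
            n_total = len(growths[0])
            n_window = w.mask(growths[0].frame.index).sum()
            n_missing_outside = (
                growths[0].frame["G"].isna() & ~w.mask(growths[0].frame.index)
            ).sum()
            # every window row was withheld from training, nothing else
            assert captured["n"] == n_total - n_window - n_missing_outside
            assert np.isfinite(captured["y"]).all()
        finally:
            dg.ALGORITHMS.pop("probe", None)

    def test_network_applicability_below_full_when_references_gappy(self):
        # the reference tree has its own 20-day sensor failure overlapping
        # the June window, so network interpolation must refuse there
        params = dg.SimParams(years=(2020,), noise_sd=1.0, seed=17)
        bundles = dg.simulate_network(
            2, rho=1.0, params_base=params,
            gap_specs=[[], [("2020-06-05", 20 * 48)]],
        )
        gs = [dg.zero_growth(b[0]) for b in bundles]
        ds = BenchmarkDataset("t0", [gs[0]])
        res = dg.run_benchmark(
            [ds], methods=["network"], references=[gs[1]],
            windows=dg.make_artificial_gaps([2020]),
        )
        by_period = res.table.set_index("period").applicable
        assert not by_period["middle"]
        assert by_period["start"] and by_period["end"]

    def test_network_method_records_applicability(self):
        growths = _sim_growths(3, rho=1.0)
        datasets = [BenchmarkDataset(g.tree_id, [g]) for g in growths]
        res = dg.run_benchmark(
            datasets, methods=["network"], windows=[GapWindow("middle", 2020)]
        )
        assert res.table.applicable.all()
        assert (res.table.rmse < 5.0).all()


@pytest.fixture(scope="module")
def doy_fit():
    idx = pd.date_range("2020-01-01", periods=6000, freq="30min")
    X = pd.DataFrame(
        {
            "DOY": idx.dayofyear.astype(int),
            "hour": (idx.hour + idx.minute / 60.0).astype(float),
        }
    )
    X = dg.add_random_feature(X, seed=1)
    rng = np.random.default_rng(0)
    y = pd.Series(400 / (1 + np.exp(-0.25 * (X["DOY"] - 60))) + rng.normal(0, 1, len(X)))
    norm = dg.fit_normalizer(X)
    fit = dg.train_model(dg.apply_normalizer(X, norm), y, seed=0, norm=norm)
    return fit, dg.apply_normalizer(X, norm), y


class TestPermutationImportance:
    def test_boot_permutations_per_feature(self, doy_fit):
        fit, X, y = doy_fit
        res = dg.permutation_importance(fit, X, y, boot=50, seed=0)
        assert res.samples.shape == (50, 3)
        assert res.n_permutations == 50

    def test_label_driving_feature_dominates(self, doy_fit):
        fit, X, y = doy_fit
        res = dg.permutation_importance(fit, X, y, boot=20, seed=0)
        assert res.means.idxmax() == "DOY"
        assert res.means["DOY"] > 1.0  # permuted models have negative R²

    def test_random_feature_importance_is_negligible(self, doy_fit):
        fit, X, y = doy_fit
        res = dg.permutation_importance(fit, X, y, boot=20, seed=0)
        assert abs(res.means["random"]) < 0.01 * res.means["DOY"]

    def test_boot_below_one_rejected(self, doy_fit):
        fit, X, y = doy_fit
        with pytest.raises(DendrogapError):
            dg.permutation_importance(fit, X, y, boot=0)


class TestFriedman:
    def test_equal_cells_give_zero_statistic(self):
        stat, p = dg.friedman_test(np.ones((4, 3)))
        assert stat == pytest.approx(0.0)

    def test_perfect_ordering_closed_form(self):
        # k=3 methods, n=5 blocks, identical ordering: rank sums 5/10/15
        data = np.tile([1.0, 2.0, 3.0], (5, 1))
        stat, p = dg.friedman_test(data)
        assert stat == pytest.approx(10.0)

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            data = rng.normal(size=(rng.integers(3, 8), rng.integers(3, 6)))
            stat, p = dg.friedman_test(data)
            ref = scipy.stats.friedmanchisquare(*[data[:, j] for j in range(data.shape[1])])
            assert stat == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_chi_square_p_close_to_permutation_p_at_moderate_n(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(20, 3)) + np.array([0.0, 0.3, 0.6])
        stat, p_chi = dg.friedman_test(data)
        hits = 0
        n_mc = 2000
        for _ in range(n_mc):
            permuted = np.array([row[rng.permutation(3)] for row in data])
            s, _ = dg.friedman_test(permuted)
            hits += s >= stat - 1e-9
        assert abs(p_chi - hits / n_mc) < 0.05

    def test_missing_cells_rejected(self):
        data = np.ones((3, 3))
        data[0, 0] = np.nan
        with pytest.raises(DendrogapError):
            dg.friedman_test(data)

    def test_too_few_methods_rejected(self):
        with pytest.raises(DendrogapError):
            dg.friedman_test(np.ones((5, 2)))


class TestMannWhitney:
    def test_identical_samples_symmetric(self):
        U, p = dg.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert U == 4.5  # n·m/2
        assert p > 0.9

    def test_fully_separated_exact_p(self):
        U, p = dg.mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert U == 0.0
        assert p == pytest.approx(2 / scipy.special.comb(6, 3))

    def test_swapping_samples_mirrors_u_same_p(self):
        a, b = [1.0, 5.0, 2.5], [4.0, 0.5]
        U1, p1 = dg.mann_whitney_u(a, b)
        U2, p2 = dg.mann_whitney_u(b, a)
        assert U1 + U2 == len(a) * len(b)
        assert p1 == pytest.approx(p2)

    def test_exact_path_matches_scipy_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n, m = rng.integers(1, 6), rng.integers(1, 6)
            vals = rng.permutation(np.arange(1.0, n + m + 1))
            a, b = vals[:n], vals[n:]
            U, p = dg.mann_whitney_u(a, b)
            ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert U == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_large_or_tied_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 5, 30).astype(float)
        b = rng.integers(1, 6, 25).astype(float)
        U, p = dg.mann_whitney_u(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue)

    def test_empty_sample_rejected(self):
        with pytest.raises(DendrogapError):
            dg.mann_whitney_u([], [1.0])
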