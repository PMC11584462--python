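"""Evaluation harness: artificial seasonal gaps, method comparison,
permutation feature importance and nonparametric significance tests.

Three fixed 30-day windows per year probe the growing season — start
(Apr 16 – May 15), middle (Jun 1 – 30) and end (Sep 1 – 30). For every
(dataset, window) pair the window is blanked, each gap-filling method runs
on the blanked data only (ML methods retrain from scratch on everything
outside the window), and the predictions are scored by RMSE against the
withheld truth on the half-hourly grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.stats

from .baselines import network_fill, spline_fill
from .errors import DendrogapError, InsufficientDataError
from .features import FeatureMatrix, build_features, drop_constant_columns
from .gapfill import (
    ALGORITHMS,
    FitResult,
    apply_normalizer,
    fit_normalizer,
    predict_gaps,
    train_model,
)
from .types import GrowthSeries, TreeMeta

PERIOD_DATES = {
    "start": ((4, 16), (5, 15)),
    "middle": ((6, 1), (6, 30)),
    "end": ((9, 1), (9, 30)),
}
PERIODS = tuple(PERIOD_DATES)


@dataclass(frozen=True)
class GapWindow:
    """One 30-consecutive-day artificial gap."""

    period: str
    year: int

    def __post_init__(self):
        if self.period not in PERIOD_DATES:
            raise DendrogapError(f"unknown period {self.period!r}")

    @property
    def first_day(self) -> pd.Timestamp:
        m, d = PERIOD_DATES[self.period][0]
        return pd.Timestamp(year=self.year, month=m, day=d)

    @property
    def last_day(self) -> pd.Timestamp:
        m, d = PERIOD_DATES[self.period][1]
        return pd.Timestamp(year=self.year, month=m, day=d)

    @property
    def end_instant(self) -> pd.Timestamp:
        return self.last_day + pd.Timedelta(days=1) - pd.Timedelta(seconds=1)

    def mask(self, index: pd.DatetimeIndex) -> np.ndarray:
        return np.asarray((index >= self.first_day) & (index <= self.end_instant))


def make_artificial_gaps(years: Sequence[int]) -> List[GapWindow]:
    """Three fixed 30-day windows (start/middle/end of the growing season)
    for each year."""
    if len(years) == 0:
        raise DendrogapError("years must be non-empty")
    return [GapWindow(period=p, year=y) for y in years for p in PERIODS]


@dataclass
class BenchmarkDataset:
    """One comparison unit: a single tree or a grouped set of trees."""

    dataset_id: str
    trees: List[GrowthSeries]
    meta: Dict[str, TreeMeta] = field(default_factory=dict)


@dataclass
class BenchmarkResult:
    table: pd.DataFrame  # dataset, period, year, method, rmse, n_gap_points, applicable
    n_ml_fits: int
    fits: Dict[Tuple[str, str, int, str], FitResult] = field(default_factory=dict)


def _blank_window(tree: GrowthSeries, window: GapWindow) -> GrowthSeries:
    out = tree.copy()
    out.frame.loc[window.mask(out.frame.index), "G"] = np.nan
    return out


def _ml_fill_window(
    dataset: BenchmarkDataset, window: GapWindow, algorithm: str, seed: int
):
    """Retrain *algorithm* on everything outside the window and predict
    the blanked rows. Returns (per-tree predictions, truth, fit)."""
    blanked = [_blank_window(t, window) for t in dataset.trees]
    fm = build_features(blanked if len(blanked) > 1 else blanked[0], dataset.meta or None)
    in_window = window.mask(fm.timestamps)
    train_rows = ~fm.gap_mask.values
    # leakage guard: no training row may fall inside the blanked window
    assert not (train_rows & in_window).any(), "withheld rows leaked into training"
    if train_rows.sum() <= fm.X.shape[1]:
        raise InsufficientDataError("too few rows outside the window to train")
    X, _ = drop_constant_columns(fm.X)
    norm = fit_normalizer(X[train_rows])
    fit = train_model(
        apply_normalizer(X[train_rows], norm), fm.y[train_rows],
        algorithm=algorithm, seed=seed, norm=norm, compute_train_metrics=False,
    )
    gap_rows = fm.gap_mask.values & in_window
    preds = predict_gaps(fit, apply_normalizer(X[gap_rows], norm))
    out = pd.DataFrame(
        {
            "tree_id": fm.tree_id.values[gap_rows],
            "timestamp": fm.timestamps[gap_rows],
            "G_pred": preds["G_pred"].values,
        }
    )
    return out, fit


def _truth_in_window(tree: GrowthSeries, window: GapWindow) -> pd.Series:
    g = tree.frame["G"]
    return g[window.mask(g.index)].dropna()


def run_benchmark(
    datasets: Sequence[BenchmarkDataset],
    methods: Sequence[Union[str, Tuple[str, Callable]]] = ("xgb",),
    seed: int = 0,
    windows: Optional[Sequence[GapWindow]] = None,
    references: Optional[Sequence[GrowthSeries]] = None,
    min_r: float = 0.5,
    keep_fits: bool = False,
) -> BenchmarkResult:
    """Blank each artificial gap window in each dataset and score every
    method against the withheld truth.

    ``methods`` entries are registered algorithm ids (retrained per
    window), ``"spline"``, ``"network"`` (needs *references*), or
    ``(name, callable)`` pairs where ``callable(blanked_trees, window)``
    returns ``{tree_id: pd.Series}`` predictions. Windows without truth in
    a dataset's span, and network attempts without an eligible reference,
    are recorded as not applicable.
    """
    if windows is None:
        years = sorted({y for ds in datasets for t in ds.trees for y in t.timestamps.year.unique()})
        windows = make_artificial_gaps(years)
    rows = []
    n_ml_fits = 0
    fits: Dict[Tuple, FitResult] = {}
    for i, (ds, window) in enumerate(itertools.product(datasets, windows)):
        truth = {t.tree_id: _truth_in_window(t, window) for t in ds.trees}
        n_truth = sum(len(v) for v in truth.values())
        for method in methods:
            name = method if isinstance(method, str) else method[0]
            record = {
                "dataset": ds.dataset_id,
                "period": window.period,
                "year": window.year,
                "method": name,
                "rmse": np.nan,
                "n_gap_points": 0,
                "applicable": False,
            }
            if n_truth == 0:  # window outside the dataset span
                rows.append(record)
                continue
            sq_errors: List[np.ndarray] = []
            if isinstance(method, str) and method in ALGORITHMS:
                fit_seed = (seed * 1_000_003 + i) % (2**31)
                preds, fit = _ml_fill_window(ds, window, method, fit_seed)
                n_ml_fits += 1
                if keep_fits:
                    fits[(ds.dataset_id, window.period, window.year, name)] = fit
                merged = preds.set_index(["tree_id", "timestamp"])["G_pred"]
                for t in ds.trees:
                    tv = truth[t.tree_id]
                    if len(tv) == 0:
                        continue
                    p = merged.loc[t.tree_id].reindex(tv.index)
                    sq_errors.append((p.values - tv.values) ** 2)
            elif method == "spline":
                try:
                    for t in ds.trees:
                        tv = truth[t.tree_id]
                        if len(tv) == 0:
                            continue
                        filled = spline_fill(_blank_window(t, window), window)
                        p = filled["G_pred"].reindex(tv.index)
                        sq_errors.append((p.values - tv.values) ** 2)
                except InsufficientDataError:
                    sq_errors = []
            elif method == "network":
                pool = list(references) if references is not None else [
                    t for other in datasets for t in other.trees
                ]
                for t in ds.trees:
                    tv = truth[t.tree_id]
                    if len(tv) == 0:
                        continue
                    res = network_fill(_blank_window(t, window), pool, window, min_r=min_r)
                    if res.applicable:
                        p = res.predictions["G_pred"].reindex(tv.index)
                        sq_errors.append((p.values - tv.values) ** 2)
            elif callable(method[1] if isinstance(method, tuple) else None):
                blanked = [_blank_window(t, window) for t in ds.trees]
                pred_map = method[1](blanked, window)
                for t in ds.trees:
                    tv = truth[t.tree_id]
                    if len(tv) == 0 or t.tree_id not in pred_map:
                        continue
                    p = pred_map[t.tree_id].reindex(tv.index)
                    sq_errors.append((p.values - tv.values) ** 2)
            else:
                raise DendrogapError(f"unknown method {method!r}")
            if sq_errors:
                allsq = np.concatenate(sq_errors)
                allsq = allsq[np.isfinite(allsq)]
                if len(allsq):
                    record["rmse"] = float(np.sqrt(allsq.mean()))
                    record["n_gap_points"] = int(len(allsq))
                    record["applicable"] = True
            rows.append(record)
    return BenchmarkResult(table=pd.DataFrame(rows), n_ml_fits=n_ml_fits, fits=fits)


# --------------------------------------------------------------------------
# permutation feature importance


@dataclass
class PFIResult:
    """Per-feature mean ΔR² over permutations plus the raw permutation
    values. The injected random feature's PFI bounds 'no importance'."""

    means: pd.Series
    samples: pd.DataFrame  # boot rows × features
    n_permutations: int
    r2_original: float


def _plain_r2(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def permutation_importance(
    fit: FitResult,
    X: pd.DataFrame,
    y: pd.Series,
    boot: int = 50,
    seed: int = 0,
) -> PFIResult:
    """ΔR² = R²(original) − R²(column permuted), *boot* permutations per
    feature; PFI is the mean ΔR². Values above 1 occur when permutation
    drives the model's R² negative."""
    if boot < 1:
        raise DendrogapError("boot must be ≥ 1")
    rng = np.random.default_rng(seed)
    Xv = X[fit.feature_names].values.copy()
    yv = y.values.astype(float)
    r2_orig = _plain_r2(yv, fit.model.predict(Xv))
    samples = {}
    for j, name in enumerate(fit.feature_names):
        deltas = np.empty(boot)
        col = Xv[:, j].copy()
        for b in range(boot):
            Xv[:, j] = rng.permutation(col)
            deltas[b] = r2_orig - _plain_r2(yv, fit.model.predict(Xv))
        Xv[:, j] = col
        samples[name] = deltas
    table = pd.DataFrame(samples)
    return PFIResult(
        means=table.mean(), samples=table, n_permutations=boot, r2_original=r2_orig
    )


# --------------------------------------------------------------------------
# nonparametric method comparison


def friedman_test(data) -> Tuple[float, float]:
    """Classical Friedman chi-square over within-block ranks.

    *data* is an (n_blocks × k_methods) array/DataFrame with no missing
    cells; ties get mean ranks; p from the χ²(k−1) approximation.
    """
    arr = np.asarray(pd.DataFrame(data).values, dtype=float)
    n, k = arr.shape
    if k < 3:
        raise DendrogapError("Friedman test needs ≥ 3 methods")
    if n < 2:
        raise DendrogapError("Friedman test needs ≥ 2 blocks")
    if np.isnan(arr).any():
        raise DendrogapError("Friedman test requires complete blocks (no missing cells)")
    ranks = np.apply_along_axis(scipy.stats.rankdata, 1, arr)
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * float((rank_sums**2).sum()) - 3.0 * n * (k + 1)
    p = float(scipy.stats.chi2.sf(stat, k - 1))
    return float(stat), p


def mann_whitney_u(sample_a, sample_b) -> Tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    U is the count of pairs (a > b) with half-credit for ties. The p-value
    is exact (full enumeration of rank assignments) for n_a + n_b ≤ 12
    without ties, otherwise the normal approximation with tie correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DendrogapError("both samples must be non-empty")
    n, m = len(a), len(b)
    U = float((a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum())

    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == n + m
    if no_ties and n + m <= 12:
        ranks = scipy.stats.rankdata(pooled)
        total = 0
        le = ge = 0
        for combo in itertools.combinations(range(n + m), n):
            u = ranks[list(combo)].sum() - n * (n + 1) / 2.0
            total += 1
            le += u <= U
            ge += u >= U
        p = min(1.0, 2.0 * min(le, ge) / total)
        return U, float(p)
    if np.all(pooled == pooled[0]):
        return U, 1.0
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return U, float(res.pvalue)
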