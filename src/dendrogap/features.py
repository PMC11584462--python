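"""Predictor matrix construction and multicollinearity screening.

The gap-filling models regress cumulative growth on purely temporal
predictors — day of year (DOY), calendar year, fractional hour — plus, for
grouped multi-tree datasets, static site descriptors (unsealed area; tree
height for non-urban groups). A uniform-noise "random" column can be
appended as a statistical baseline for permutation feature importance.

Multicollinearity among predictors is screened with the variance inflation
factor VIF_j = 1/(1−R²_j), R²_j from regressing column j on all other
columns (with intercept); columns are removed greedily until all VIFs fall
below the threshold (5 by convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import DendrogapError, IntegrityError
from .types import GrowthSeries, TreeMeta

KNOWN_COLUMNS = ("DOY", "year", "hour", "area", "height", "random")


@dataclass
class FeatureMatrix:
    """Predictor table aligned to growth-series timestamps.

    ``gap_mask`` is True exactly where the label y (cumulative growth) is
    missing — those rows are excluded from training and are the rows to be
    imputed.
    """

    X: pd.DataFrame
    y: pd.Series
    gap_mask: pd.Series
    tree_id: pd.Series
    timestamps: pd.DatetimeIndex

    def __post_init__(self):
        n = len(self.X)
        if not (len(self.y) == len(self.gap_mask) == len(self.tree_id) == len(self.timestamps) == n):
            raise IntegrityError("feature-matrix components disagree in length")
        if not (self.gap_mask.values == self.y.isna().values).all():
            raise IntegrityError("gap_mask must be True exactly where y is missing")

    def __len__(self) -> int:
        return len(self.X)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.X.copy(), self.y.copy(), self.gap_mask.copy(),
            self.tree_id.copy(), self.timestamps.copy(),
        )


def _calendar_columns(index: pd.DatetimeIndex) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "DOY": index.dayofyear.astype(int),
            "year": index.year.astype(int),
            "hour": (index.hour + index.minute / 60.0).astype(float),
        }
    )


def build_features(
    growth: Union[GrowthSeries, Sequence[GrowthSeries]],
    meta: Union[TreeMeta, Dict[str, TreeMeta], None] = None,
    include: Union[str, Sequence[str]] = "auto",
) -> FeatureMatrix:
    """Build the predictor matrix for one tree or a grouped set of trees.

    ``include="auto"`` uses DOY/year/hour always; for grouped inputs it
    adds ``area``, and additionally ``height`` when every tree is
    non-urban with a recorded height (constant-per-tree columns carry no
    information for a single tree and are dropped there). An explicit
    list of column names overrides auto selection.
    """
    trees = [growth] if isinstance(growth, GrowthSeries) else list(growth)
    if isinstance(meta, TreeMeta):
        meta = {meta.tree_id: meta}
    meta = meta or {}

    if include == "auto":
        cols = ["DOY", "year", "hour"]
        if len(trees) > 1:
            metas = [meta.get(t.tree_id) for t in trees]
            if any(m is None for m in metas):
                raise DendrogapError("grouped feature building requires metadata for every tree")
            cols.append("area")
            if all(m.environment == "non-urban" and m.height is not None for m in metas):
                cols.append("height")
    else:
        cols = list(include)
        unknown = set(cols) - set(KNOWN_COLUMNS)
        if unknown:
            raise DendrogapError(f"unknown feature column(s) {sorted(unknown)}")
        if "random" in cols:
            raise DendrogapError("use add_random_feature() to append the random baseline")

    frames, ys, ids, stamps = [], [], [], []
    for t in trees:
        part = _calendar_columns(t.timestamps)
        m = meta.get(t.tree_id)
        if "area" in cols:
            if m is None:
                raise DendrogapError(f"no metadata for tree {t.tree_id!r} (area requested)")
            part["area"] = m.unsealed_area
        if "height" in cols:
            if m is None or m.height is None:
                raise DendrogapError(f"no height for tree {t.tree_id!r}")
            part["height"] = m.height
        frames.append(part[cols])
        ys.append(t.frame["G"].reset_index(drop=True))
        ids.append(pd.Series([t.tree_id] * len(t), dtype=object))
        stamps.append(pd.Series(t.timestamps))

    X = pd.concat(frames, ignore_index=True)
    y = pd.concat(ys, ignore_index=True).rename("y")
    return FeatureMatrix(
        X=X,
        y=y,
        gap_mask=y.isna().rename("gap_mask"),
        tree_id=pd.concat(ids, ignore_index=True).rename("tree_id"),
        timestamps=pd.DatetimeIndex(pd.concat(stamps, ignore_index=True), name="timestamp"),
    )


def _vif(values: np.ndarray, j: int) -> float:
    """VIF of column *j*: regress it on the other columns plus intercept."""
    yj = values[:, j]
    others = np.delete(values, j, axis=1)
    A = np.column_stack([np.ones(len(yj)), others])
    coef, _, _, _ = np.linalg.lstsq(A, yj, rcond=None)
    resid = yj - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((yj - yj.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_screen(
    X: pd.DataFrame, threshold: float = 5.0
) -> Tuple[List[str], pd.DataFrame]:
    """Iteratively drop the predictor with the largest VIF until all are
    below *threshold*.

    Ties are broken by removing the later column in declaration order.
    Returns the retained column names and a table of the final VIFs.
    Constant columns must be removed by the caller first.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        raise DendrogapError("VIF screening needs at least 2 columns")
    if len(X) <= len(cols):
        raise DendrogapError("VIF screening needs more rows than columns")
    for c in cols:
        if np.nanstd(X[c].values.astype(float)) == 0:
            raise DendrogapError(f"constant column {c!r}: drop it before VIF screening")
    values = X[cols].values.astype(float)
    while len(cols) >= 2:
        vifs = np.array([_vif(values, j) for j in range(len(cols))])
        worst = np.flatnonzero(vifs == vifs.max())[-1]  # later column on ties
        if vifs[worst] < threshold:
            break
        cols.pop(worst)
        values = np.delete(values, worst, axis=1)
    if len(cols) == 1:
        table = pd.DataFrame({"feature": cols, "vif": [1.0]})
    else:
        table = pd.DataFrame(
            {"feature": cols, "vif": [_vif(values, j) for j in range(len(cols))]}
        )
    return cols, table


def drop_constant_columns(X: pd.DataFrame):
    """Return (X without zero-variance columns, dropped names). Constant
    predictors carry no information and break z-normalization; e.g. 'year'
    within a single-year dataset."""
    sd = X.std(ddof=0)
    dropped = [c for c in X.columns if sd[c] == 0]
    if len(dropped) == len(X.columns):
        raise DendrogapError("all feature columns are constant")
    return X.drop(columns=dropped), dropped


def add_random_feature(
    fm: Union[FeatureMatrix, pd.DataFrame], seed: int
) -> Union[FeatureMatrix, pd.DataFrame]:
    """Append an i.i.d. Uniform(0, 1) column named ``random``, reproducible
    from *seed*. It serves as the no-importance baseline in permutation
    feature importance."""
    rng = np.random.default_rng(seed)
    if isinstance(fm, pd.DataFrame):
        out = fm.copy()
        out["random"] = rng.uniform(size=len(out))
        return out
    out = fm.copy()
    out.X["random"] = rng.uniform(size=len(out.X))
    return out
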