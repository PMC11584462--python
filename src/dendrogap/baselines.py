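"""Reference gap fillers to benchmark the model-based approach against.

- :func:`spline_fill`: cubic smoothing spline through a few days of
  observations on each flank of the gap. Purely local; can produce
  decreasing "growth" across step-like onsets — deliberately not
  suppressed, since surfacing that failure mode is part of the comparison.
- :func:`network_fill`: regression transfer from the best-correlated
  neighbouring tree. Requires a reference tree with complete data inside
  the gap and high co-variance outside it; when no such neighbour exists
  the result is "not applicable" rather than an error, and the benchmark
  records the applicability rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .errors import DendrogapError, InsufficientDataError
from .types import FLAG_NETWORK, FLAG_SPLINE, GrowthSeries


def _gap_bounds(gap) -> tuple:
    """Accept a GapWindow-like object or a (start, end) timestamp pair."""
    if hasattr(gap, "first_day"):
        return pd.Timestamp(gap.first_day), pd.Timestamp(gap.last_day) + pd.Timedelta(
            days=1
        ) - pd.Timedelta(seconds=1)
    start, end = gap
    return pd.Timestamp(start), pd.Timestamp(end)


def spline_fill(
    growth: GrowthSeries,
    gap,
    anchor_days: float = 5.0,
    smoothing: Optional[float] = None,
) -> pd.DataFrame:
    """Fill a gap by a cubic smoothing spline fitted to *anchor_days* of
    flanking observations on each side.

    *smoothing* is passed to :class:`scipy.interpolate.UnivariateSpline`
    (None = scipy's default smoothing). Raises if either flank has no
    observed values — extrapolation is not attempted.
    """
    start, end = _gap_bounds(gap)
    g = growth.frame["G"]
    inside = (g.index >= start) & (g.index <= end)
    if not inside.any():
        return pd.DataFrame({"G_pred": [], "source_flag": []}, index=pd.DatetimeIndex([]))
    pad = pd.Timedelta(days=anchor_days)
    left = g[(g.index >= start - pad) & (g.index < start)].dropna()
    right = g[(g.index > end) & (g.index <= end + pad)].dropna()
    if len(left) < 4 or len(right) < 4:
        raise InsufficientDataError(
            "spline fill needs observed anchors on both flanks of the gap"
        )
    anchors = pd.concat([left, right])
    t0 = anchors.index[0]
    x = (anchors.index - t0).total_seconds().values / 3600.0
    spl = UnivariateSpline(x, anchors.values, k=3, s=smoothing)
    ts = g.index[inside]
    xg = (ts - t0).total_seconds().values / 3600.0
    return pd.DataFrame({"G_pred": spl(xg), "source_flag": FLAG_SPLINE}, index=ts)


@dataclass
class NetworkFillResult:
    """Outcome of a network-interpolation attempt. ``applicable=False``
    (with a reason) is a legitimate result, distinct from failure."""

    applicable: bool
    predictions: Optional[pd.DataFrame] = None
    reference_id: Optional[str] = None
    correlation: Optional[float] = None
    slope: Optional[float] = None
    intercept: Optional[float] = None
    reason: Optional[str] = None


def network_fill(
    target: GrowthSeries,
    references: Sequence[GrowthSeries],
    gap,
    min_r: float = 0.5,
    min_overlap: int = 48,
    multi_reference: bool = False,
) -> NetworkFillResult:
    """Fill a gap in *target* from the best-correlated reference tree.

    Eligible references have no missing values inside the gap window. The
    reference with the highest Pearson correlation to the target over
    their common non-missing span outside the gap is chosen (must reach
    *min_r*); the target is regressed on it by OLS with intercept and the
    regression predicts the gap. ``multi_reference=True`` averages the OLS
    predictions of all references reaching *min_r* instead.
    """
    start, end = _gap_bounds(gap)
    gt = target.frame["G"]
    inside = (gt.index >= start) & (gt.index <= end)
    outside_mask = ~inside & gt.notna().values

    scored = []
    for ref in references:
        if ref.tree_id == target.tree_id:
            continue
        gr = ref.frame["G"].reindex(gt.index)
        if gr[inside].isna().any():
            continue  # reference must be complete inside the gap
        both = outside_mask & gr.notna().values
        if both.sum() < min_overlap:
            continue
        r = float(np.corrcoef(gt.values[both], gr.values[both])[0, 1])
        if np.isfinite(r):
            scored.append((r, ref, gr, both))
    if not scored:
        return NetworkFillResult(applicable=False, reason="no complete reference inside the gap window")
    scored.sort(key=lambda t: t[0], reverse=True)
    eligible = [s for s in scored if s[0] >= min_r]
    if not eligible:
        return NetworkFillResult(
            applicable=False,
            reason=f"best reference correlation {scored[0][0]:.2f} below min_r={min_r}",
        )

    ts = gt.index[inside]
    chosen = eligible if multi_reference else eligible[:1]
    preds = []
    for r, ref, gr, both in chosen:
        slope, intercept = np.polyfit(gr.values[both], gt.values[both], deg=1)
        preds.append(intercept + slope * gr[inside].values)
    pred = np.mean(preds, axis=0)
    r0, ref0, gr0, both0 = chosen[0]
    slope0, intercept0 = np.polyfit(gr0.values[both0], gt.values[both0], deg=1)
    return NetworkFillResult(
        applicable=True,
        predictions=pd.DataFrame({"G_pred": pred, "source_flag": FLAG_NETWORK}, index=ts),
        reference_id=ref0.tree_id,
        correlation=r0,
        slope=float(slope0),
        intercept=float(intercept0),
    )
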