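"""Quality control of raw dendrometer and temperature records.

Three stages:

1. :func:`screen_temperature` — plausibility screen of the air-temperature
   record (physical range plus spike test against both neighbours).
2. :func:`detect_jumps` / :func:`correct_jumps` — robust detection of
   abrupt sensor shifts ("jumps") in the stem-radius series via a
   MAD-of-first-differences rule, with a frost guard: a sudden radius drop
   coinciding with near-or-sub-zero temperature is genuine frost shrinkage
   and must not be corrected away.
3. :func:`fill_short_gaps` — linear interpolation of missing runs of at
   most 24 points (12 h on the half-hourly grid); longer runs are left for
   the model-based gap filler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .errors import DendrogapError, InsufficientDataError
from .types import ClimateSeries, DendroSeries, FLAG_LINEAR, FLAG_OBSERVED, FLAG_REMOVED


@dataclass
class JumpEvent:
    """An abrupt shift: ``index`` is the grid position of the first
    post-jump value; ``offset`` the signed step size in µm."""

    index: int
    timestamp: pd.Timestamp
    offset: float
    frost_guarded: bool = False


def screen_temperature(
    climate: ClimateSeries,
    tmin: float = -40.0,
    tmax: float = 50.0,
    max_step: float = 10.0,
) -> ClimateSeries:
    """Blank implausible temperatures: outside [tmin, tmax] °C, or spikes
    differing by more than *max_step* °C from **both** neighbours."""
    out = climate.copy()
    t = out.frame["temperature"].values.astype(float)
    bad = (t < tmin) | (t > tmax)
    prev = np.roll(t, 1)
    nxt = np.roll(t, -1)
    spike = (np.abs(t - prev) > max_step) & (np.abs(t - nxt) > max_step)
    spike[0] = spike[-1] = False
    t[bad | spike] = np.nan
    out.frame["temperature"] = t
    return out


def detect_jumps(
    series: DendroSeries,
    climate: Optional[ClimateSeries] = None,
    diff_threshold_mad: float = 10.0,
    frost_temp: float = 5.0,
) -> List[JumpEvent]:
    """Flag first differences larger than ``diff_threshold_mad`` × MAD of
    all first differences.

    A flagged *negative* difference at a timestamp whose air temperature is
    at or below *frost_temp* °C is returned with ``frost_guarded=True``:
    frost-induced shrinkage looks like a downward jump but is real.
    Without a climate series the frost guard is disabled (with a warning).
    """
    r = series.radius.values.astype(float)
    if np.isfinite(r).sum() < 10:
        raise InsufficientDataError("need ≥ 10 non-missing points to detect jumps")
    d = np.diff(r)  # NaN wherever either neighbour is missing
    finite = np.isfinite(d)
    dv = d[finite]
    mad = np.median(np.abs(dv - np.median(dv)))
    if mad == 0:  # near-constant series: fall back to the mean absolute deviation
        mad = np.mean(np.abs(dv - np.median(dv)))
    if mad == 0:
        return []
    thr = diff_threshold_mad * mad

    if climate is None:
        warnings.warn("no climate series: frost guard disabled", stacklevel=2)
        temp_at = None
    else:
        temp_at = climate.frame["temperature"].reindex(series.timestamps)

    events: List[JumpEvent] = []
    for pos in np.flatnonzero(np.isfinite(d) & (np.abs(d) > thr)):
        idx = int(pos) + 1  # first post-jump value
        ts = series.timestamps[idx]
        guarded = False
        if d[pos] < 0 and temp_at is not None:
            t_here = temp_at.iloc[idx]
            if np.isfinite(t_here) and t_here <= frost_temp:
                guarded = True
        events.append(JumpEvent(index=idx, timestamp=ts, offset=float(d[pos]), frost_guarded=guarded))
    return events


def correct_jumps(
    series: DendroSeries, events: List[JumpEvent], mode: str = "subtract"
) -> DendroSeries:
    """Remove non-frost-guarded jumps.

    ``mode="subtract"`` (default) subtracts each event's offset from all
    values from the event index onward, re-levelling the series.
    ``mode="delete"`` instead blanks the segment from the event index to
    the next event (or series end) and flags it ``removed``.
    Frost-guarded events are never touched.
    """
    if mode not in ("subtract", "delete"):
        raise DendrogapError(f"unknown jump-correction mode {mode!r}")
    out = series.copy()
    r = out.frame["radius"].values.astype(float)
    n = len(r)
    active = [e for e in events if not e.frost_guarded]
    for e in active:
        if not (0 < e.index < n):
            raise DendrogapError(f"jump index {e.index} out of range")
    if mode == "subtract":
        for e in active:
            r[e.index :] -= e.offset
    else:
        bounds = sorted(e.index for e in active) + [n]
        flags = out.frame["source_flag"].values.copy()
        for e in active:
            stop = min(b for b in bounds if b > e.index)
            r[e.index : stop] = np.nan
            flags[e.index : stop] = FLAG_REMOVED
        out.frame["source_flag"] = flags
    out.frame["radius"] = r
    return out


def _missing_runs(mask: np.ndarray):
    """Yield (start, stop) of maximal True runs in *mask* (stop exclusive)."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    yield from zip(starts.tolist(), stops.tolist())


def fill_short_gaps(series: DendroSeries, max_points: int = 24) -> DendroSeries:
    """Linearly interpolate every maximal missing run of ≤ *max_points*
    points that has observed values on both flanks.

    24 points is 12 h on the half-hourly grid — the conventional limit
    beyond which straight-line filling misrepresents diurnal dynamics.
    Longer runs, and runs touching either series end, stay missing.
    Observed values are never altered.
    """
    out = series.copy()
    r = out.frame["radius"].values.astype(float)
    flags = out.frame["source_flag"].values.copy()
    n = len(r)
    for start, stop in _missing_runs(~np.isfinite(r)):
        if stop - start > max_points or start == 0 or stop == n:
            continue
        left, right = r[start - 1], r[stop]
        frac = np.arange(1, stop - start + 1) / (stop - start + 1)
        r[start:stop] = left + frac * (right - left)
        flags[start:stop] = FLAG_LINEAR
    out.frame["radius"] = r
    out.frame["source_flag"] = flags
    return out
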