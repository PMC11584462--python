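"""Zero-growth model: partition a cleaned stem-radius series into
irreversible cumulative growth G and reversible tree water deficit TWD.

With ``M(t)`` the running maximum of the radius up to ``t`` (skipping
missing slots)::

    G(t)   = M(t) − radius(t₀)
    TWD(t) = M(t) − radius(t)

so that ``radius(t) = radius(t₀) + G(t) − TWD(t)`` exactly at every
non-missing point. Growth occurs only when the radius exceeds its previous
maximum; shrinkage below the maximum is attributed to stem water status.

The model does not know about winter bark-cell degradation, which can
masquerade as off-season growth; :func:`winter_correction` cancels growth
increments outside the plausible season (DOY 60–304 by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .types import DendroSeries, GrowthSeries, QC_NEGATIVE, QC_OK, QC_WINTER


def zero_growth(series: DendroSeries, restart_annually: bool = False) -> GrowthSeries:
    """Apply the zero-growth partition to a cleaned series.

    Missing radius slots yield missing G and TWD (no interpolation).
    With ``restart_annually=True`` the running maximum (and G) restarts at
    zero each calendar year; the default accumulates from the series start.
    """
    r = series.radius
    if r.notna().sum() == 0:
        raise InsufficientDataError("all-missing series")
    if restart_annually:
        parts = []
        for _, chunk in r.groupby(series.timestamps.year):
            m = chunk.cummax()
            first = chunk.dropna().iloc[0] if chunk.notna().any() else np.nan
            parts.append(pd.DataFrame({"G": m - first, "twd": m - chunk}))
        frame = pd.concat(parts)
        frame["qc_flag"] = QC_OK
        out = GrowthSeries(series.tree_id, frame, series.step)
        # annual restarts legitimately reset G; skip the global monotonic check
        from .types import check_grid

        check_grid(frame.index, series.step)
        return out
    m = r.cummax()
    r0 = r.dropna().iloc[0]
    out = GrowthSeries.from_arrays(
        series.tree_id, series.timestamps, (m - r0).values, (m - r).values, step=series.step
    )
    return out.check_invariants()


def winter_correction(
    growth: GrowthSeries,
    start_doy: int = 60,
    end_doy: int = 304,
    mode: str = "cancel",
) -> GrowthSeries:
    """Remove implausible off-season growth from a zero-growth output.

    Negative G values (possible only in externally produced input) are set
    missing and flagged ``negative_removed``. Growth increments landing at
    DOY < *start_doy* or DOY > *end_doy* are handled per *mode*:

    - ``"cancel"`` (default): the increment is cancelled — G is held at its
      prior value and all later values shift down accordingly; affected
      slots are flagged ``winter_corrected``.
    - ``"delete"``: every off-season slot whose G exceeds the last
      in-season value is blanked instead.

    The result remains non-decreasing over non-missing points.
    """
    out = growth.copy()
    g = out.frame["G"].values.astype(float)
    qc = out.frame["qc_flag"].values.copy()

    neg = np.isfinite(g) & (g < 0)
    g[neg] = np.nan
    qc[neg] = QC_NEGATIVE

    doy = np.asarray(growth.timestamps.dayofyear)
    winter = (doy < start_doy) | (doy > end_doy)
    pos = np.flatnonzero(np.isfinite(g))
    if len(pos):
        v = g[pos]
        inc = np.diff(v, prepend=v[0])
        cancel = winter[pos] & (inc > 0)
        if mode == "cancel":
            inc[cancel] = 0.0
            g[pos] = v[0] + np.cumsum(inc) - inc[0]
            qc[pos[cancel]] = QC_WINTER
        elif mode == "delete":
            # blank winter slots that sit above the last kept in-season level
            drop = np.zeros(len(pos), dtype=bool)
            level = v[0]
            for j in range(len(pos)):
                if winter[pos[j]] and v[j] > level + 1e-12:
                    drop[j] = True
                else:
                    level = v[j]
            g[pos[drop]] = np.nan
            qc[pos[drop]] = QC_WINTER
        else:
            raise ValueError(f"unknown winter-correction mode {mode!r}")
    out.frame["G"] = g
    out.frame["qc_flag"] = qc
    return out.check_invariants()
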