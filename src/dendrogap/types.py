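"""Core domain containers.

All time series in this package live on a regular time grid (30-minute step
by default, matching common dendrometer logger configuration). Gaps are
explicit: a missing measurement occupies its grid slot as NaN rather than
being absent from the record. Every container validates its own invariants
so that downstream stages can assume grid regularity.

Units: stem radius and derived quantities (cumulative growth G, tree water
deficit TWD) are micrometres; temperature is degrees Celsius; relative
humidity is percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import GridError, IntegrityError

# provenance flags for radius/growth values
FLAG_OBSERVED = "observed"
FLAG_LINEAR = "linear_fill"
FLAG_ML = "ml_fill"
FLAG_SPLINE = "spline_fill"
FLAG_NETWORK = "network_fill"
FLAG_REMOVED = "removed"
SOURCE_FLAGS = (
    FLAG_OBSERVED,
    FLAG_LINEAR,
    FLAG_ML,
    FLAG_SPLINE,
    FLAG_NETWORK,
    FLAG_REMOVED,
)

# quality-control flags for zero-growth output
QC_OK = "ok"
QC_WINTER = "winter_corrected"
QC_NEGATIVE = "negative_removed"
QC_FLAGS = (QC_OK, QC_WINTER, QC_NEGATIVE)

DEFAULT_STEP = pd.Timedelta(minutes=30)

#: Maximum unsealed ground area credited to a single tree, m².  Fully
#: unsealed sites are capped here so the predictor stays bounded.
MAX_UNSEALED_AREA_M2 = 144.0


def check_grid(index: pd.DatetimeIndex, step: pd.Timedelta) -> None:
    """Raise :class:`GridError` unless *index* is strictly increasing with
    constant spacing *step*."""
    if not isinstance(index, pd.DatetimeIndex):
        raise GridError("timestamps must be a DatetimeIndex")
    if index.tz is not None:
        raise GridError("timestamps must be timezone-naive")
    if len(index) > 1:
        deltas = np.diff(index.asi8)
        want = int(step / pd.Timedelta(nanoseconds=1))
        if (deltas <= 0).any():
            bad = index[1:][deltas <= 0][0]
            raise GridError(f"timestamps not strictly increasing at {bad}")
        if (deltas != want).any():
            bad = index[1:][deltas != want][0]
            raise GridError(
                f"grid step is not a constant {step} (first offender {bad})"
            )


def _as_float(values, n: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise IntegrityError(f"{name} has shape {arr.shape}, expected ({n},)")
    if np.isinf(arr).any():
        raise IntegrityError(f"{name} contains non-finite (infinite) values")
    return arr


def _as_flags(flags, n: int, allowed: tuple, default: str) -> pd.Series:
    if flags is None:
        return pd.Series([default] * n, dtype=object)
    out = pd.Series(list(flags), dtype=object)
    if len(out) != n:
        raise IntegrityError(f"flag vector length {len(out)} != {n}")
    bad = set(out.unique()) - set(allowed)
    if bad:
        raise IntegrityError(f"unknown flags {sorted(bad)}")
    return out


@dataclass
class DendroSeries:
    """A stem-radius record for one tree on a regular grid.

    ``frame`` is indexed by timestamp and carries ``radius`` (µm, NaN for
    missing slots) and ``source_flag`` (provenance of each value).
    """

    tree_id: str
    frame: pd.DataFrame
    step: pd.Timedelta = DEFAULT_STEP

    @classmethod
    def from_arrays(
        cls,
        tree_id: str,
        timestamps,
        radius,
        flags=None,
        step: pd.Timedelta = DEFAULT_STEP,
    ) -> "DendroSeries":
        index = pd.DatetimeIndex(timestamps, name="timestamp")
        frame = pd.DataFrame(
            {
                "radius": _as_float(radius, len(index), "radius"),
                "source_flag": _as_flags(flags, len(index), SOURCE_FLAGS, FLAG_OBSERVED).values,
            },
            index=index,
        )
        out = cls(tree_id=tree_id, frame=frame, step=step)
        out.validate()
        return out

    # -- accessors -----------------------------------------------------
    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def radius(self) -> pd.Series:
        return self.frame["radius"]

    @property
    def flags(self) -> pd.Series:
        return self.frame["source_flag"]

    def __len__(self) -> int:
        return len(self.frame)

    def copy(self) -> "DendroSeries":
        return DendroSeries(self.tree_id, self.frame.copy(), self.step)

    def validate(self) -> "DendroSeries":
        check_grid(self.frame.index, self.step)
        _as_float(self.frame["radius"].values, len(self.frame), "radius")
        _as_flags(self.frame["source_flag"], len(self.frame), SOURCE_FLAGS, FLAG_OBSERVED)
        return self

    def equals(self, other: "DendroSeries") -> bool:
        return (
            self.tree_id == other.tree_id
            and self.step == other.step
            and self.frame.index.equals(other.frame.index)
            and np.array_equal(
                self.frame["radius"].values, other.frame["radius"].values, equal_nan=True
            )
            and (self.frame["source_flag"].values == other.frame["source_flag"].values).all()
        )


@dataclass
class ClimateSeries:
    """Air temperature (°C) and relative humidity (%) on the same grid
    convention as :class:`DendroSeries`."""

    frame: pd.DataFrame
    step: pd.Timedelta = DEFAULT_STEP

    @classmethod
    def from_arrays(
        cls, timestamps, temperature, rh=None, step: pd.Timedelta = DEFAULT_STEP
    ) -> "ClimateSeries":
        index = pd.DatetimeIndex(timestamps, name="timestamp")
        n = len(index)
        if rh is None:
            rh = np.full(n, np.nan)
        frame = pd.DataFrame(
            {
                "temperature": _as_float(temperature, n, "temperature"),
                "rh": _as_float(rh, n, "rh"),
            },
            index=index,
        )
        out = cls(frame=frame, step=step)
        out.validate()
        return out

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def temperature(self) -> pd.Series:
        return self.frame["temperature"]

    @property
    def rh(self) -> pd.Series:
        return self.frame["rh"]

    def __len__(self) -> int:
        return len(self.frame)

    def copy(self) -> "ClimateSeries":
        return ClimateSeries(self.frame.copy(), self.step)

    def validate(self) -> "ClimateSeries":
        check_grid(self.frame.index, self.step)
        rh = self.frame["rh"]
        bad = rh[(rh.notna()) & ((rh < 0) | (rh > 100))]
        if len(bad):
            raise IntegrityError(
                f"relative humidity outside [0, 100] at {bad.index[0]}"
            )
        return self


@dataclass
class TreeMeta:
    """Static per-tree metadata used as model predictors."""

    tree_id: str
    species: str  # "maple" | "plane"
    environment: str  # "urban" | "non-urban"
    unsealed_area: float  # m², capped at MAX_UNSEALED_AREA_M2
    dbh: float  # diameter at breast height, cm
    height: Optional[float] = None  # m

    def __post_init__(self):
        if self.species not in ("maple", "plane"):
            raise IntegrityError(f"unknown species {self.species!r}")
        if self.environment not in ("urban", "non-urban"):
            raise IntegrityError(f"unknown environment {self.environment!r}")
        # fully unsealed sites are recorded at the cap, never above it
        self.unsealed_area = float(min(self.unsealed_area, MAX_UNSEALED_AREA_M2))
        if not (0 < self.unsealed_area <= MAX_UNSEALED_AREA_M2):
            raise IntegrityError("unsealed_area must be in (0, 144] m²")


@dataclass
class GrowthSeries:
    """Zero-growth-model output: cumulative growth G and tree water deficit
    TWD (both µm), with a per-slot QC flag.

    On non-missing points of the input the reconstruction identity holds:
    ``radius(t) = radius(t0) + G(t) - TWD(t)``.
    """

    tree_id: str
    frame: pd.DataFrame  # columns: G, twd, qc_flag
    step: pd.Timedelta = DEFAULT_STEP

    @classmethod
    def from_arrays(
        cls,
        tree_id: str,
        timestamps,
        G,
        twd,
        qc=None,
        step: pd.Timedelta = DEFAULT_STEP,
    ) -> "GrowthSeries":
        index = pd.DatetimeIndex(timestamps, name="timestamp")
        n = len(index)
        frame = pd.DataFrame(
            {
                "G": _as_float(G, n, "G"),
                "twd": _as_float(twd, n, "twd"),
                "qc_flag": _as_flags(qc, n, QC_FLAGS, QC_OK).values,
            },
            index=index,
        )
        out = cls(tree_id=tree_id, frame=frame, step=step)
        out.validate()
        return out

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def G(self) -> pd.Series:
        return self.frame["G"]

    @property
    def twd(self) -> pd.Series:
        return self.frame["twd"]

    @property
    def qc(self) -> pd.Series:
        return self.frame["qc_flag"]

    def __len__(self) -> int:
        return len(self.frame)

    def copy(self) -> "GrowthSeries":
        return GrowthSeries(self.tree_id, self.frame.copy(), self.step)

    def validate(self) -> "GrowthSeries":
        """Structural checks (grid regularity). Model-filled series may
        legitimately contain non-monotone predictions, so the zero-growth
        invariants are enforced separately via :meth:`check_invariants`
        by the operations that guarantee them."""
        check_grid(self.frame.index, self.step)
        return self

    def check_invariants(self) -> "GrowthSeries":
        """Zero-growth invariants: G non-decreasing and TWD ≥ 0 over
        non-missing points."""
        self.validate()
        g = self.frame["G"].dropna()
        if len(g) > 1 and (np.diff(g.values) < -1e-9).any():
            raise IntegrityError("G must be non-decreasing over non-missing points")
        twd = self.frame["twd"].dropna()
        if len(twd) and (twd.values < -1e-9).any():
            raise IntegrityError("TWD must be non-negative")
        return self

    def equals(self, other: "GrowthSeries") -> bool:
        return (
            self.tree_id == other.tree_id
            and self.frame.index.equals(other.frame.index)
            and np.array_equal(self.frame["G"].values, other.frame["G"].values, equal_nan=True)
            and np.array_equal(self.frame["twd"].values, other.frame["twd"].values, equal_nan=True)
            and (self.frame["qc_flag"].values == other.frame["qc_flag"].values).all()
        )
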