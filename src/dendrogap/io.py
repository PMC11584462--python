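"""CSV readers/writers and grid utilities.

Dialect: comma-separated, header row required, ISO-8601 timezone-naive
timestamps, missing values as empty fields. Readers regularize onto the
declared grid: slots between the first and last timestamp that are absent
from the file become explicit NaN rows.

File layouts::

    dendrometer: timestamp,radius_um[,source_flag]
    climate:     timestamp,temp_c,rh_pct
    growth:      timestamp,g_um,twd_um[,qc_flag]
    metadata:    tree_id,species,environment,area_m2,dbh_cm,height_m
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import EmptyOverlapError, FormatError, IntegrityError
from .types import (
    DEFAULT_STEP,
    ClimateSeries,
    DendroSeries,
    FLAG_OBSERVED,
    GrowthSeries,
    QC_OK,
    TreeMeta,
)

_UNIT_TO_UM = {"um": 1.0, "µm": 1.0, "mm": 1e3, "cm": 1e4, "m": 1e6}


def _parse_timestamps(raw: pd.Series, path) -> pd.DatetimeIndex:
    try:
        ts = pd.to_datetime(raw, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamps ({exc})") from None
    if ts.isna().any():
        bad = raw[ts.isna()].iloc[0]
        raise FormatError(f"{path}: unparseable timestamp {bad!r}")
    dup = ts.duplicated()
    if dup.any():
        raise IntegrityError(f"{path}: duplicate timestamp {ts[dup].iloc[0]}")
    return pd.DatetimeIndex(ts, name="timestamp")


def _regularize(frame: pd.DataFrame, step: pd.Timedelta, path) -> pd.DataFrame:
    """Reindex onto the full grid spanned by the file; absent slots → NaN."""
    if len(frame) == 0:
        return frame
    if not frame.index.is_monotonic_increasing:
        frame = frame.sort_index()
    grid = pd.date_range(frame.index[0], frame.index[-1], freq=step, name="timestamp")
    off = frame.index.difference(grid)
    if len(off):
        raise IntegrityError(f"{path}: timestamp {off[0]} is not on the {step} grid")
    return frame.reindex(grid)


def read_dendro_csv(
    path: Union[str, Path],
    grid_step: pd.Timedelta = DEFAULT_STEP,
    tree_id: Optional[str] = None,
    unit: str = "um",
) -> DendroSeries:
    """Read a dendrometer CSV into a grid-regularized :class:`DendroSeries`.

    ``unit`` declares the radius unit in the file; values are converted to
    µm internally.
    """
    path = Path(path)
    if unit not in _UNIT_TO_UM:
        raise FormatError(f"unknown radius unit {unit!r}")
    raw = pd.read_csv(path, dtype={"source_flag": "object"})
    if "timestamp" not in raw.columns or "radius_um" not in raw.columns:
        raise FormatError(f"{path}: expected columns timestamp,radius_um")
    index = _parse_timestamps(raw["timestamp"], path)
    frame = pd.DataFrame(
        {"radius": pd.to_numeric(raw["radius_um"], errors="coerce").values * _UNIT_TO_UM[unit]},
        index=index,
    )
    frame["source_flag"] = (
        raw["source_flag"].fillna(FLAG_OBSERVED).values
        if "source_flag" in raw.columns
        else FLAG_OBSERVED
    )
    frame = _regularize(frame, grid_step, path)
    frame["source_flag"] = frame["source_flag"].fillna(FLAG_OBSERVED)
    return DendroSeries.from_arrays(
        tree_id or path.stem,
        frame.index,
        frame["radius"].values,
        frame["source_flag"].values,
        step=grid_step,
    )


def write_series(series: DendroSeries, path: Union[str, Path]) -> None:
    """Write a :class:`DendroSeries`; round-trips through
    :func:`read_dendro_csv` exactly, including flags and missingness."""
    series.validate()
    out = pd.DataFrame(
        {
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "radius_um": series.radius.map(lambda v: "" if pd.isna(v) else repr(float(v))),
            "source_flag": series.flags.values,
        }
    )
    out.to_csv(path, index=False)


def read_climate_csv(
    path: Union[str, Path], grid_step: pd.Timedelta = DEFAULT_STEP
) -> ClimateSeries:
    path = Path(path)
    raw = pd.read_csv(path)
    if "timestamp" not in raw.columns or "temp_c" not in raw.columns:
        raise FormatError(f"{path}: expected columns timestamp,temp_c[,rh_pct]")
    index = _parse_timestamps(raw["timestamp"], path)
    frame = pd.DataFrame(
        {
            "temperature": pd.to_numeric(raw["temp_c"], errors="coerce").values,
            "rh": pd.to_numeric(raw.get("rh_pct", np.nan), errors="coerce"),
        },
        index=index,
    )
    frame = _regularize(frame, grid_step, path)
    return ClimateSeries.from_arrays(
        frame.index, frame["temperature"].values, frame["rh"].values, step=grid_step
    )


def write_climate(series: ClimateSeries, path: Union[str, Path]) -> None:
    series.validate()
    fmt = lambda v: "" if pd.isna(v) else repr(float(v))
    pd.DataFrame(
        {
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "temp_c": series.temperature.map(fmt),
            "rh_pct": series.rh.map(fmt),
        }
    ).to_csv(path, index=False)


def read_growth_csv(
    path: Union[str, Path],
    grid_step: pd.Timedelta = DEFAULT_STEP,
    tree_id: Optional[str] = None,
) -> GrowthSeries:
    path = Path(path)
    raw = pd.read_csv(path, dtype={"qc_flag": "object"})
    need = {"timestamp", "g_um", "twd_um"}
    if not need <= set(raw.columns):
        raise FormatError(f"{path}: expected columns timestamp,g_um,twd_um[,qc_flag]")
    index = _parse_timestamps(raw["timestamp"], path)
    frame = pd.DataFrame(
        {
            "G": pd.to_numeric(raw["g_um"], errors="coerce").values,
            "twd": pd.to_numeric(raw["twd_um"], errors="coerce").values,
            "qc_flag": raw.get("qc_flag", pd.Series(QC_OK, index=raw.index)).fillna(QC_OK).values,
        },
        index=index,
    )
    frame = _regularize(frame, grid_step, path)
    frame["qc_flag"] = frame["qc_flag"].fillna(QC_OK)
    return GrowthSeries.from_arrays(
        tree_id or path.stem,
        frame.index,
        frame["G"].values,
        frame["twd"].values,
        frame["qc_flag"].values,
        step=grid_step,
    )


def write_growth(series: GrowthSeries, path: Union[str, Path]) -> None:
    series.validate()
    fmt = lambda v: "" if pd.isna(v) else repr(float(v))
    pd.DataFrame(
        {
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "g_um": series.G.map(fmt),
            "twd_um": series.twd.map(fmt),
            "qc_flag": series.qc.values,
        }
    ).to_csv(path, index=False)


def read_meta_csv(path: Union[str, Path]) -> dict[str, TreeMeta]:
    """Read the per-tree metadata table into ``{tree_id: TreeMeta}``."""
    raw = pd.read_csv(path)
    need = {"tree_id", "species", "environment", "area_m2", "dbh_cm"}
    if not need <= set(raw.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}[,height_m]")
    out = {}
    for _, row in raw.iterrows():
        h = row.get("height_m")
        out[str(row["tree_id"])] = TreeMeta(
            tree_id=str(row["tree_id"]),
            species=row["species"],
            environment=row["environment"],
            unsealed_area=float(row["area_m2"]),
            dbh=float(row["dbh_cm"]),
            height=None if pd.isna(h) else float(h),
        )
    return out


def write_meta(meta: dict[str, TreeMeta], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "tree_id": m.tree_id,
                "species": m.species,
                "environment": m.environment,
                "area_m2": m.unsealed_area,
                "dbh_cm": m.dbh,
                "height_m": "" if m.height is None else m.height,
            }
            for m in meta.values()
        ]
    ).to_csv(path, index=False)


def align(series_a, series_b):
    """Restrict two grid series to their common overlapping span.

    Works for any pair of the container types in :mod:`dendrogap.types`.
    Raises :class:`EmptyOverlapError` if the spans are disjoint.
    """
    if series_a.step != series_b.step:
        raise IntegrityError("cannot align series with different grid steps")
    ia, ib = series_a.frame.index, series_b.frame.index
    start, end = max(ia[0], ib[0]), min(ia[-1], ib[-1])
    if start > end:
        raise EmptyOverlapError(
            f"series spans {ia[0]}–{ia[-1]} and {ib[0]}–{ib[-1]} do not overlap"
        )
    out_a, out_b = series_a.copy(), series_b.copy()
    out_a.frame = series_a.frame.loc[start:end]
    out_b.frame = series_b.frame.loc[start:end]
    if len(out_a.frame) != len(out_b.frame):  # same step + same span ⇒ same grid
        raise IntegrityError("aligned series disagree on the common grid")
    return out_a, out_b
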