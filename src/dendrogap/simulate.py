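"""Synthetic dendrometer data generator.

Emulates the statistical structure the processing pipeline assumes:
multi-year half-hourly stem-radius series with a sigmoidal seasonal
cumulative-growth curve, diurnal shrink–swell cycles (tree water deficit),
Gaussian sensor noise, technical jumps, frost episodes and missing runs of
configurable length — for one tree or a network of trees with tunable
inter-tree correlation of growth increments.

Every simulated bundle returns the noise-free ground truth alongside the
"measured" series, so detection and imputation stages can be scored
exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import SpecError
from .types import (
    DEFAULT_STEP,
    ClimateSeries,
    DendroSeries,
    GrowthSeries,
    TreeMeta,
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class SimParams:
    """Parameters of one simulated tree-year block.

    The seasonal cumulative-growth curve is a symmetric double sigmoid in
    day of year: half the annual amplitude is accrued around ``onset_doy``
    and half around ``cessation_doy``, each with logistic steepness
    ``steepness`` (1/day). The curve is ≈0 before onset and ≈``amplitude``
    after cessation, and accumulates across years.
    """

    years: Sequence[int] = (2020, 2021)
    amplitude: float = 500.0        # annual radial growth, µm
    onset_doy: float = 110.0
    cessation_doy: float = 280.0
    steepness: float = 0.12         # 1/day
    twd_amplitude: float = 60.0     # peak diurnal shrinkage, µm
    noise_sd: float = 2.0           # sensor noise, µm
    jump_spec: Sequence[Tuple] = ()      # (timestamp, offset µm)
    gap_spec: Sequence[Tuple] = ()       # (start timestamp, length in points)
    frost_episodes: Sequence[Tuple] = () # (start timestamp, length in points)
    frost_threshold: float = 5.0    # °C; frost episodes sit below this
    seed: int = 0
    tree_id: str = "T000"
    baseline_um: float = 10_000.0   # arbitrary sensor zero offset
    step: pd.Timedelta = DEFAULT_STEP
    # climate shape
    temp_mean: float = 10.8
    temp_seasonal_amp: float = 10.0
    temp_diurnal_amp: float = 4.0
    temp_noise_sd: float = 0.8

    def validate(self) -> "SimParams":
        if len(self.years) < 1:
            raise SpecError("need at least one simulation year")
        if list(self.years) != sorted(set(self.years)):
            raise SpecError("years must be strictly increasing")
        if not self.onset_doy < self.cessation_doy:
            raise SpecError("onset_doy must precede cessation_doy")
        if self.amplitude < 0 or self.noise_sd < 0 or self.twd_amplitude < 0:
            raise SpecError("amplitude, noise_sd and twd_amplitude must be ≥ 0")
        if self.steepness <= 0:
            raise SpecError("steepness must be positive")
        return self


def seasonal_growth_curve(doy_fraction, year_index, params: SimParams):
    """Cumulative seasonal growth (µm) at fractional day-of-year
    *doy_fraction* of year number *year_index* (0-based).

    Double-sigmoid: ``A/2·[σ(k(d−onset)) + σ(k(d−cessation))]`` plus one
    full amplitude per completed year, so multi-year curves accumulate
    continuously.
    """
    params.validate()
    d = np.asarray(doy_fraction, dtype=float)
    k, a = params.steepness, params.amplitude
    within = 0.5 * a * (
        _sigmoid(k * (d - params.onset_doy)) + _sigmoid(k * (d - params.cessation_doy))
    )
    return np.asarray(year_index, dtype=float) * a + within


def _grid(params: SimParams) -> pd.DatetimeIndex:
    start = pd.Timestamp(year=min(params.years), month=1, day=1)
    end = pd.Timestamp(year=max(params.years), month=12, day=31, hour=23, minute=30)
    return pd.date_range(start, end, freq=params.step, name="timestamp")


def _calendar(index: pd.DatetimeIndex, first_year: int):
    doy_frac = index.dayofyear + (index.hour + index.minute / 60.0) / 24.0
    year_index = index.year - first_year
    return np.asarray(doy_frac), np.asarray(year_index)


def _season_activity(doy, params: SimParams):
    """Growing-season activity in [0, 1]: ≈1 mid-season, →0 in winter."""
    k = params.steepness
    return _sigmoid(k * (doy - params.onset_doy)) * _sigmoid(
        -k * (doy - params.cessation_doy)
    )


def _diurnal_shrink(hour):
    """Unit diurnal shrinkage profile: zero at night, peak mid-afternoon."""
    h = np.asarray(hour, dtype=float)
    return np.clip(np.sin(np.pi * (h - 8.0) / 14.0), 0.0, None) * ((h >= 8) & (h <= 22))


def _tree_rng(seed: int, tree_id: str) -> np.random.Generator:
    # one independent stream per tree: adding trees never perturbs existing ones
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(tree_id.encode())]))


def _simulate_with_growth(
    params: SimParams, G_true: np.ndarray, index: pd.DatetimeIndex
):
    """Assemble the measured radius / truth / climate / metadata bundle
    around a prescribed cumulative-growth path."""
    rng = _tree_rng(params.seed, params.tree_id)
    doy, _ = _calendar(index, min(params.years))
    hour = np.asarray(index.hour + index.minute / 60.0, dtype=float)

    # reversible diurnal water deficit, tapering outside the growing season
    season = 0.15 + 0.85 * _season_activity(doy, params)
    twd_true = params.twd_amplitude * season * _diurnal_shrink(hour)

    noise = rng.normal(0.0, params.noise_sd, len(index)) if params.noise_sd > 0 else 0.0
    radius = params.baseline_um + G_true - twd_true + noise

    for instant, offset in params.jump_spec:
        radius = radius + float(offset) * (index >= pd.Timestamp(instant))

    # blank the configured missing runs
    missing = np.zeros(len(index), dtype=bool)
    for start, length in params.gap_spec:
        pos = index.searchsorted(pd.Timestamp(start))
        run = slice(pos, min(pos + int(length), len(index)))
        if missing[run].any():
            raise SpecError(f"gap runs overlap at {start}")
        missing[run] = True
    radius = np.where(missing, np.nan, radius)

    dendro = DendroSeries.from_arrays(params.tree_id, index, radius, step=params.step)
    truth = GrowthSeries.from_arrays(
        params.tree_id, index, G_true, twd_true, step=params.step
    ).check_invariants()

    # climate: seasonal + diurnal temperature, noise, forced frost episodes
    t_seas = params.temp_mean - params.temp_seasonal_amp * np.cos(
        2 * np.pi * (doy - 15.0) / 365.25
    )
    t_diur = -params.temp_diurnal_amp * np.cos(2 * np.pi * (hour - 14.0) / 24.0)
    temp = t_seas + t_diur + rng.normal(0.0, params.temp_noise_sd, len(index))
    for start, length in params.frost_episodes:
        pos = index.searchsorted(pd.Timestamp(start))
        temp[pos : pos + int(length)] = params.frost_threshold - 6.0
    rh = np.clip(70.0 - 2.0 * t_diur + rng.normal(0.0, 3.0, len(index)), 5.0, 100.0)
    climate = ClimateSeries.from_arrays(index, temp, rh, step=params.step)

    meta = TreeMeta(
        tree_id=params.tree_id,
        species=["maple", "plane"][rng.integers(2)],
        environment=["urban", "non-urban"][rng.integers(2)],
        unsealed_area=float(np.round(rng.uniform(2.0, 160.0), 2)),  # capped in TreeMeta
        dbh=float(np.round(rng.uniform(20.0, 90.0), 1)),
        height=float(np.round(rng.uniform(8.0, 25.0), 1)),
    )
    return dendro, truth, climate, meta


def simulate_tree(params: SimParams):
    """Simulate one tree.

    Returns ``(DendroSeries, GrowthSeries truth, ClimateSeries, TreeMeta)``.
    The measured radius is ``baseline + G_true − TWD_true + noise`` with jump
    offsets added cumulatively from each jump instant onward and the
    configured gap runs blanked; the truth series has no missingness.
    """
    params.validate()
    index = _grid(params)
    doy, year_index = _calendar(index, min(params.years))
    G_true = seasonal_growth_curve(doy, year_index, params)
    G_true = G_true - G_true[0]  # growth is measured from the series start
    return _simulate_with_growth(params, G_true, index)


def simulate_network(
    n_trees: int,
    rho: float,
    params_base: SimParams,
    amplitudes: Optional[Sequence[float]] = None,
    gap_specs: Optional[Sequence[Sequence[Tuple]]] = None,
):
    """Simulate a network of trees with correlated growth increments.

    Each tree's half-hourly growth increment is the blend
    ``rho·common + (1−rho)·individual``, where the common component is the
    deterministic seasonal curve and the individual component is a random
    non-negative increment process (daily exponential weights, normalized
    to the same annual amplitude). ``rho=1`` gives identical curve shapes
    up to amplitude; ``rho=0`` gives uncorrelated increments.
    """
    if n_trees < 1:
        raise SpecError("n_trees must be ≥ 1")
    if not 0.0 <= rho <= 1.0:
        raise SpecError("rho must be in [0, 1]")
    params_base.validate()
    index = _grid(params_base)
    doy, year_index = _calendar(index, min(params_base.years))

    bundles = []
    for i in range(n_trees):
        tree_id = f"T{i:03d}"
        p = SimParams(**{**params_base.__dict__, "tree_id": tree_id})
        amp = params_base.amplitude if amplitudes is None else float(amplitudes[i])
        p.amplitude = amp
        if gap_specs is not None:
            p.gap_spec = tuple(gap_specs[i])

        common = seasonal_growth_curve(doy, year_index, p)

        if rho == 1.0:  # exact path, bit-identical to simulate_tree
            bundles.append(_simulate_with_growth(p, common - common[0], index))
            continue
        common_inc = np.diff(common, prepend=common[0])

        rng = _tree_rng(p.seed, tree_id + "/walk")
        # daily exponential weights spread evenly over each day's slots
        days = np.asarray((index.normalize() - index[0].normalize()).days)
        n_days = days[-1] + 1
        w = rng.exponential(1.0, n_days)
        slots_per_day = np.bincount(days, minlength=n_days)
        per_slot = w[days] / slots_per_day[days]
        n_years = len(p.years)
        indiv_inc = per_slot / per_slot.sum() * amp * n_years
        inc = rho * common_inc + (1.0 - rho) * indiv_inc
        G_true = np.cumsum(inc)
        G_true -= G_true[0]
        bundles.append(_simulate_with_growth(p, G_true, index))
    return bundles
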