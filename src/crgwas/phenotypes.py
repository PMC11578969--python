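"""Climatic-resilience (CR) indicators from longitudinal vaginal temperature.

Twelve indicators are derived per animal from a nominally regular 10-minute
vaginal-temperature (Tv) series:

* LnVar, lag-1 autocorrelation, and skewness of the deviations between each
  observation and the mean (``Ave``) or median (``Med``) of a trailing moving
  window of six consecutive observations — six indicators;
* Max_Tv: daily maximum Tv, aggregated over days;
* HSD: daily minutes with Tv above the ventilation-specific heat-stress (HS)
  threshold, aggregated over days;
* HSU_A / HSU_B: summed Tv deviations above / at-or-below the HS threshold
  over the whole recording period;
* Nor_avevar / Nor_medvar: min-max-normalized animal-level mean/median Tv
  multiplied by min-max-normalized Tv variance (population-level scaling).

Windows and lag-1 pairs must be contiguous on the nominal sampling grid
(default tolerance +/-2 min); sensor gaps split the series rather than being
interpolated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

INDICATOR_COLUMNS = [
    "LnVar_Ave",
    "LnVar_Med",
    "Autocor_Ave",
    "Autocor_Med",
    "Skew_Ave",
    "Skew_Med",
    "Max_Tv",
    "HSD",
    "HSU_A",
    "HSU_B",
    "Nor_avevar",
    "Nor_medvar",
]


@dataclass
class TvSeries:
    """One animal's vaginal-temperature record.

    Timestamps sit on a nominally regular 10-min grid but may have holes;
    they must be strictly increasing and Tv finite wherever present.
    """

    animal_id: str
    timestamps: np.ndarray  # datetime64
    tv: np.ndarray          # degC
    ventilation: str        # "mechanical" | "natural"
    parity: int
    barn_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[m]")
        self.tv = np.asarray(self.tv, dtype=float)
        if self.timestamps.shape != self.tv.shape:
            raise ValueError("timestamps and tv must have equal length")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= np.timedelta64(0, "m")):
            raise ValueError(f"{self.animal_id}: timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.tv)):
            raise ValueError(f"{self.animal_id}: tv must be finite")
        if self.ventilation not in ("mechanical", "natural"):
            raise ValueError(f"unknown ventilation class {self.ventilation!r}")

    def __len__(self) -> int:
        return len(self.tv)


@dataclass
class DeviationSeries:
    """Deviations of each observation from its trailing-window statistic."""

    animal_id: str
    timestamps: np.ndarray
    deviations: np.ndarray
    window_stat: str  # "average" | "median"
    interval_min: int = 10
    gap_tolerance_min: int = 2


@dataclass
class HSConfig:
    """Heat-stress thresholds and windowing parameters.

    Thresholds are ventilation-class specific Tv cutoffs (degC) above which
    an animal is considered heat-stressed; defaults are the values estimated
    for mechanically (39.76) and naturally (39.78) ventilated barns.
    """

    threshold_mechanical: float = 39.76
    threshold_natural: float = 39.78
    window_length: int = 6
    interval: int = 10          # minutes between nominal observations
    gap_tolerance: int = 2      # minutes of slack when testing contiguity
    min_run_length: int = 1     # minimum consecutive exceedances for HSD
    max_tv_aggregate: str = "mean"   # mean | median | max over days
    hsd_aggregate: str = "mean"
    hsu_b_absolute: bool = False     # report |HSU_B| instead of the signed sum

    def __post_init__(self) -> None:
        for thr in (self.threshold_mechanical, self.threshold_natural):
            if not (35.0 < thr < 45.0):
                raise ValueError(f"HS threshold {thr} outside (35, 45) degC")
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")

    def threshold_for(self, ventilation: str) -> float:
        if ventilation == "mechanical":
            return self.threshold_mechanical
        if ventilation == "natural":
            return self.threshold_natural
        raise ValueError(f"unknown ventilation class {ventilation!r}")


def _contiguous_steps(timestamps: np.ndarray, interval: int, tolerance: int) -> np.ndarray:
    """Boolean mask: step t-1 -> t is on the nominal grid (within tolerance)."""
    if len(timestamps) < 2:
        return np.zeros(0, dtype=bool)
    gaps = np.diff(timestamps) / np.timedelta64(1, "m")
    return np.abs(gaps - interval) <= tolerance


def window_deviations(
    series: TvSeries,
    stat: str = "average",
    window_length: int = 6,
    interval: int = 10,
    gap_tolerance: int = 2,
) -> DeviationSeries:
    """Deviation of each observation from its trailing moving window.

    For every time point ``t`` with a complete trailing window of
    ``window_length`` consecutive on-grid observations ending at (and
    including) ``t``, the deviation is ``tv(t) - stat(window)``.  Windows
    spanning a gap produce no deviation.
    """
    if stat not in ("average", "median"):
        raise ValueError(f"stat must be 'average' or 'median', got {stat!r}")
    n = len(series)
    if n < window_length:
        warnings.warn(
            f"{series.animal_id}: series shorter than window ({n} < {window_length}); "
            "empty deviation series",
            stacklevel=2,
        )
        return DeviationSeries(
            series.animal_id,
            series.timestamps[:0],
            np.zeros(0),
            stat,
            interval,
            gap_tolerance,
        )
    ok = _contiguous_steps(series.timestamps, interval, gap_tolerance)
    # window ending at index i (i >= w-1) is valid iff the w-1 steps inside it are all on-grid
    step_windows = np.lib.stride_tricks.sliding_window_view(ok, window_length - 1)
    valid = step_windows.all(axis=1)
    windows = np.lib.stride_tricks.sliding_window_view(series.tv, window_length)
    center = windows.mean(axis=1) if stat == "average" else np.median(windows, axis=1)
    dev = series.tv[window_length - 1 :] - center
    return DeviationSeries(
        series.animal_id,
        series.timestamps[window_length - 1 :][valid],
        dev[valid],
        stat,
        interval,
        gap_tolerance,
    )


def ln_variance(devs: DeviationSeries) -> float:
    """Natural log of the sample variance (n-1 denominator) of deviations.

    Returns NaN (flagged, not -inf) for fewer than two deviations or zero
    variance.
    """
    d = devs.deviations
    if len(d) < 2:
        return np.nan
    v = np.var(d, ddof=1)
    if v <= 0:
        return np.nan
    return float(np.log(v))


def lag1_autocorrelation(devs: DeviationSeries) -> float:
    """Pearson correlation between deviation(t) and deviation(t+1).

    Only pairs of deviations adjacent on the nominal grid are used; pairs
    spanning gaps are excluded.  NaN when fewer than 3 usable deviations or
    either margin is degenerate.
    """
    d = devs.deviations
    if len(d) < 3:
        return np.nan
    ok = _contiguous_steps(devs.timestamps, devs.interval_min, devs.gap_tolerance_min)
    x, y = d[:-1][ok], d[1:][ok]
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def skewness(devs: DeviationSeries) -> float:
    """Moment skewness g1 = m3 / m2^(3/2) with n-denominator central moments."""
    d = devs.deviations
    if len(d) < 3 or np.var(d) == 0:
        return np.nan
    return float(stats.skew(d, bias=True))


def _daily_groups(series: TvSeries):
    days = series.timestamps.astype("datetime64[D]")
    uniq, inverse = np.unique(days, return_inverse=True)
    return uniq, inverse


def daily_max_tv(series: TvSeries, aggregate: str = "mean") -> tuple[pd.Series, float]:
    """Daily maximum Tv and its per-animal aggregate.

    Days with no observations are omitted (never scored zero).  The
    per-animal aggregate (default: mean of daily maxima) is the value that
    enters association analysis.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    uniq, inverse = _daily_groups(series)
    maxima = np.full(len(uniq), -np.inf)
    np.maximum.at(maxima, inverse, series.tv)
    daily = pd.Series(maxima, index=uniq, name="max_tv")
    return daily, float(_aggregate(maxima, aggregate))


def _aggregate(values: np.ndarray, how: str) -> float:
    if how == "mean":
        return float(np.mean(values))
    if how == "median":
        return float(np.median(values))
    if how == "max":
        return float(np.max(values))
    raise ValueError(f"unknown aggregate {how!r}")


def hs_duration(series: TvSeries, cfg: HSConfig) -> tuple[pd.Series, float]:
    """Daily heat-stress duration (minutes above threshold) and aggregate.

    Counts observations strictly above the animal's ventilation-class
    threshold, in runs of grid-consecutive exceedances of length >=
    ``min_run_length``, times the sampling interval.  Bounded by 1440
    min/day.
    """
    thr = cfg.threshold_for(series.ventilation)
    above = series.tv > thr
    ok = _contiguous_steps(series.timestamps, cfg.interval, cfg.gap_tolerance)
    counted = np.zeros(len(series), dtype=bool)
    i = 0
    n = len(series)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] and ok[j]:
            j += 1
        if j - i + 1 >= cfg.min_run_length:
            counted[i : j + 1] = True
        i = j + 1
    uniq, inverse = _daily_groups(series)
    minutes = np.zeros(len(uniq))
    np.add.at(minutes, inverse, counted * float(cfg.interval))
    daily = pd.Series(minutes, index=uniq, name="hsd_minutes")
    return daily, float(_aggregate(minutes, cfg.hsd_aggregate))


def heat_stress_units(series: TvSeries, cfg: HSConfig) -> tuple[float, float]:
    """Summed Tv deviations above (HSU_A) and at-or-below (HSU_B) threshold.

    HSU_A >= 0 sums ``tv - thr`` over observations strictly above the
    threshold across the whole recording period; HSU_B <= 0 is the analogous
    signed sum over the remaining observations (absolute value if
    ``cfg.hsu_b_absolute``).
    """
    thr = cfg.threshold_for(series.ventilation)
    delta = series.tv - thr
    hsu_a = float(delta[delta > 0].sum())
    hsu_b = float(delta[delta <= 0].sum())
    if cfg.hsu_b_absolute:
        hsu_b = abs(hsu_b)
    return hsu_a, hsu_b


def normalized_variance_products(summary: pd.DataFrame) -> pd.DataFrame:
    """Population-level min-max normalized mean/median Tv times Tv variance.

    ``summary`` needs per-animal columns ``med`` (median Tv), ``ave`` (mean
    Tv), ``var`` (Tv variance).  For animal i,

        Nor_medvar_i = norm(med_i) * norm(var_i)
        Nor_avevar_i = norm(ave_i) * norm(var_i)

    where norm(x) = (x - min)/(max - min) over the population.  Undefined
    (error) for fewer than two animals or a zero range.
    """
    if len(summary) < 2:
        raise ValueError("population-level normalization needs >= 2 animals")

    def norm(col: pd.Series) -> pd.Series:
        rng = col.max() - col.min()
        if rng <= 0:
            raise ValueError(f"zero range for {col.name!r}: normalization undefined")
        return (col - col.min()) / rng

    out = pd.DataFrame(index=summary.index)
    nvar = norm(summary["var"])
    out["Nor_medvar"] = norm(summary["med"]) * nvar
    out["Nor_avevar"] = norm(summary["ave"]) * nvar
    return out


def derive_all_indicators(series: list[TvSeries], cfg: HSConfig | None = None) -> pd.DataFrame:
    """One row per animal with the 12 CR indicators plus covariates.

    Missing indicator values (degenerate series) are NaN-flagged, never
    silently zeroed.  Duplicate animal ids are rejected.
    """
    if not series:
        raise ValueError("empty cohort")
    if cfg is None:
        cfg = HSConfig()
    ids = [s.animal_id for s in series]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate animal ids in cohort")

    rows = []
    for s in series:
        row: dict = {"animal_id": s.animal_id}
        for stat, tag in (("average", "Ave"), ("median", "Med")):
            devs = window_deviations(
                s, stat, cfg.window_length, cfg.interval, cfg.gap_tolerance
            )
            row[f"LnVar_{tag}"] = ln_variance(devs)
            row[f"Autocor_{tag}"] = lag1_autocorrelation(devs)
            row[f"Skew_{tag}"] = skewness(devs)
        _, row["Max_Tv"] = daily_max_tv(s, cfg.max_tv_aggregate)
        _, row["HSD"] = hs_duration(s, cfg)
        row["HSU_A"], row["HSU_B"] = heat_stress_units(s, cfg)
        row["med"] = float(np.median(s.tv))
        row["ave"] = float(np.mean(s.tv))
        row["var"] = float(np.var(s.tv, ddof=1)) if len(s) > 1 else np.nan
        row["parity"] = s.parity
        row["ventilation"] = s.ventilation
        row["barn"] = s.barn_id
        rows.append(row)
    table = pd.DataFrame(rows).set_index("animal_id")
    nor = normalized_variance_products(table[["med", "ave", "var"]])
    table = table.join(nor).drop(columns=["med", "ave", "var"])
    n_missing = int(table[INDICATOR_COLUMNS].isna().sum().sum())
    if n_missing:
        log.warning("%d missing indicator values flagged as NA", n_missing)
    return table[INDICATOR_COLUMNS + ["parity", "ventilation", "barn"]]
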