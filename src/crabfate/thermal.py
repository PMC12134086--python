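"""Thermal stress from in situ temperature loggers.

Implements the NOAA Coral Reef Watch Degree Heating Week (DHW) convention on
logger data: calendar-day means, daily "hotspots" (anomalies above the maximum
monthly mean, MMM, counted only when >= 1 degC), and DHW as the rolling 84-day
(12-week) hotspot sum divided by 7, in degC-weeks.  The bleaching threshold is
MMM + 1 degC.  DHW levels of 4 and 8 degC-weeks are the conventional bleaching
and mortality alert benchmarks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

DHW_WINDOW_DAYS = 84
HOTSPOT_CUTOFF = 1.0  # degC above MMM before a day accumulates stress
PLAUSIBLE_RANGE = (10.0, 40.0)
MAX_GAP_DAYS = 2  # longest daily-mean gap bridged by linear interpolation


@dataclass
class TemperatureSeries:
    """Timestamped logger readings (degC) for one site."""

    frame: pd.DataFrame  # columns: timestamp, temp_c
    site: str = "logger"

    def __post_init__(self) -> None:
        if not {"timestamp", "temp_c"} <= set(self.frame.columns):
            raise ValidationError("temperature frame needs 'timestamp' and 'temp_c' columns")
        ts = pd.to_datetime(self.frame["timestamp"])
        if len(ts) == 0:
            raise ValidationError("empty temperature series")
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValidationError("timestamps must be strictly increasing")
        self.frame = pd.DataFrame({"timestamp": ts, "temp_c": self.frame["temp_c"].astype(float)})

    @classmethod
    def from_csv(cls, path: str | Path, site: str | None = None) -> "TemperatureSeries":
        frame = pd.read_csv(path)
        return cls(frame, site=site or Path(path).stem)

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(path, index=False)

    def flag_implausible(self) -> pd.Series:
        """Boolean mask of readings outside the plausible 10-40 degC band."""
        lo, hi = PLAUSIBLE_RANGE
        t = self.frame["temp_c"]
        return (t < lo) | (t > hi)


@dataclass
class ThermalStressResult:
    """Daily means, hotspots and DHW derived from one logger series."""

    mmm: float
    daily: pd.DataFrame  # index: date; columns: daily_mean, hotspot, dhw, flagged
    site: str = "logger"
    partial: bool = False  # series shorter than one full 84-day window

    @property
    def threshold(self) -> float:
        return bleaching_threshold(self.mmm)

    @property
    def max_dhw(self) -> float:
        d = self.daily["dhw"].dropna()
        return float(d.max()) if len(d) else float("nan")

    def to_csv(self, path: str | Path) -> None:
        out = self.daily.reset_index().rename(columns={"index": "date"})
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)

    def summary(self) -> dict:
        first4 = first_exceedance(self, 4.0)
        first8 = first_exceedance(self, 8.0)
        return {
            "site": self.site,
            "mmm_c": self.mmm,
            "bleaching_threshold_c": self.threshold,
            "max_dhw_cweeks": None if np.isnan(self.max_dhw) else round(self.max_dhw, 3),
            "first_dhw_ge_4": None if first4 is None else str(first4),
            "first_dhw_ge_8": None if first8 is None else str(first8),
            "n_days": int(len(self.daily)),
            "partial_window": self.partial,
        }


def bleaching_threshold(mmm: float) -> float:
    """Bleaching threshold: 1 degC above the maximum monthly mean."""
    if not np.isfinite(mmm):
        raise ValueError("MMM must be finite")
    return mmm + 1.0


def daily_means(series: TemperatureSeries) -> pd.DataFrame:
    """Calendar-day arithmetic means with a coverage flag.

    Days providing fewer than half the readings expected at the series'
    (median) logging interval are flagged rather than dropped.
    """
    frame = series.frame
    if len(frame) == 0:
        raise ValidationError("empty temperature series")
    ts = frame["timestamp"]
    if len(ts) > 1:
        interval_s = float(ts.diff().dt.total_seconds().median())
    else:
        interval_s = 86400.0
    expected = max(1, int(round(86400.0 / interval_s)))
    grouped = frame.groupby(ts.dt.date)["temp_c"]
    out = pd.DataFrame(
        {
            "daily_mean": grouped.mean(),
            "n_readings": grouped.size(),
        }
    )
    out["flagged"] = out["n_readings"] < 0.5 * expected
    out.index = pd.to_datetime(out.index)
    out.index.name = "date"
    return out


def _bridge_short_gaps(mean: pd.Series, max_gap: int) -> pd.Series:
    """Linearly interpolate interior NaN runs no longer than ``max_gap`` days.

    Longer runs are left missing in full (pandas' ``limit=`` would bridge the
    leading days of a long run, silently shortening it).
    """
    filled = mean.interpolate(method="linear", limit_area="inside")
    isna = mean.isna().to_numpy()
    out = mean.copy()
    run_start = None
    for i, missing in enumerate(list(isna) + [False]):
        if missing and run_start is None:
            run_start = i
        elif not missing and run_start is not None:
            if i - run_start <= max_gap:
                out.iloc[run_start:i] = filled.iloc[run_start:i]
            run_start = None
    return out


def compute_dhw(
    daily: pd.DataFrame | pd.Series, mmm: float, site: str = "logger"
) -> ThermalStressResult:
    """Hotspot and Degree Heating Week series from daily means.

    ``hotspot_d = (T_d - MMM)`` where the anomaly is >= 1 degC, else 0;
    ``dhw_t = (1/7) * sum of hotspots over the trailing 84 days`` (degC-weeks).
    The first 83 days carry NaN (no full window).  Missing or flagged days are
    bridged by linear interpolation when the gap is at most 2 days; longer
    gaps leave NaN hotspots, and every window touching them stays NaN rather
    than being silently truncated.  A series shorter than 84 days yields an
    all-NaN DHW column with ``partial=True``.
    """
    if isinstance(daily, pd.Series):
        daily = daily.to_frame(name="daily_mean")
    if len(daily) == 0:
        raise ValidationError("no daily values")
    daily = daily.copy()
    daily.index = pd.to_datetime(daily.index)
    full_index = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
    mean = daily["daily_mean"].reindex(full_index)
    if "flagged" in daily.columns:
        mean[daily["flagged"].reindex(full_index, fill_value=False)] = np.nan
    mean = _bridge_short_gaps(mean, MAX_GAP_DAYS)

    anomaly = mean - mmm
    hotspot = anomaly.where(anomaly >= HOTSPOT_CUTOFF, 0.0)
    hotspot[mean.isna()] = np.nan

    partial = len(full_index) < DHW_WINDOW_DAYS
    if partial:
        dhw = pd.Series(np.nan, index=full_index)
    else:
        dhw = hotspot.rolling(DHW_WINDOW_DAYS, min_periods=DHW_WINDOW_DAYS).sum() / 7.0

    out = pd.DataFrame(
        {
            "daily_mean": mean,
            "hotspot": hotspot,
            "dhw": dhw,
            "flagged": mean.isna(),
        },
        index=full_index,
    )
    out.index.name = "date"
    return ThermalStressResult(mmm=mmm, daily=out, site=site, partial=partial)


def thermal_stress(series: TemperatureSeries, mmm: float) -> ThermalStressResult:
    """Convenience: daily means then DHW for one logger series."""
    return compute_dhw(daily_means(series), mmm, site=series.site)


def first_exceedance(result: ThermalStressResult, level: float):
    """Earliest date with DHW >= ``level`` degC-weeks, or None."""
    d = result.daily["dhw"]
    hits = d[d >= level]
    return None if hits.empty else hits.index[0].date()


def write_summary(results: list[ThermalStressResult], path: str | Path) -> None:
    payload = {r.site: r.summary() for r in results}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
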