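"""Thermal-stress metrics from daily sea-surface temperature series.

The degree-heating-week (DHW) machinery follows the standard reef
monitoring convention: a monthly climatology yields the maximum monthly
mean (MMM); daily anomalies above the MMM are "HotSpots"; HotSpots of at
least ``hotspot_floor`` °C (1.0 °C by default) accumulate, divided by 7,
over a trailing 12-week (84-day) window to give °C-weeks.  DHW of
4 °C-weeks flags widespread-bleaching risk and 8 °C-weeks widespread-
mortality risk.
"""

from __future__ import annotations

import calendar
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

__all__ = [
    "SSTSeries",
    "Climatology",
    "DHWSeries",
    "read_sst",
    "write_dhw",
    "monthly_climatology",
    "hotspot_series",
    "dhw_series",
    "alert_level",
    "ALERT_NONE",
    "ALERT_BLEACHING",
    "ALERT_MORTALITY",
]

ALERT_NONE = "none"
ALERT_BLEACHING = "bleaching-risk"
ALERT_MORTALITY = "mortality-risk"

_SST_MIN, _SST_MAX = -2.0, 40.0


@dataclass(frozen=True)
class SSTSeries:
    """Daily SST at one location, as a pandas Series on a DatetimeIndex."""

    location: str
    values: pd.Series  # °C, daily DatetimeIndex

    def __post_init__(self) -> None:
        idx = self.values.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValidationError("SST series index must be datetimes")
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValidationError("SST dates must be strictly increasing")
        v = self.values.to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValidationError("SST series contains missing values")
        if (v < _SST_MIN).any() or (v > _SST_MAX).any():
            raise ValidationError(
                f"SST outside sanity bounds [{_SST_MIN}, {_SST_MAX}] °C"
            )

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.values.index

    def gaps(self) -> pd.DatetimeIndex:
        """Calendar days missing between the first and last observation."""
        full = pd.date_range(self.dates[0], self.dates[-1], freq="D")
        return full.difference(self.dates)


@dataclass(frozen=True)
class Climatology:
    """Monthly mean SSTs (January..December) and their maximum (MMM)."""

    location: str
    monthly_means: tuple[float, ...]  # 12 values, °C

    def __post_init__(self) -> None:
        if len(self.monthly_means) != 12:
            raise ValidationError("need exactly 12 monthly means")

    @property
    def mmm(self) -> float:
        return float(max(self.monthly_means))

    @classmethod
    def from_mmm(cls, location: str, mmm: float) -> "Climatology":
        """Climatology known only through an externally supplied MMM."""
        return cls(location, tuple([mmm] * 12))


@dataclass(frozen=True)
class DHWSeries:
    """Accumulated thermal stress (°C-weeks) per day.

    ``supported`` is False for dates whose trailing accumulation window
    extends before the start of the series (partial-window values: real,
    but underestimates of the stress a longer record would show).
    """

    location: str
    values: pd.Series  # °C-weeks
    supported: pd.Series  # bool, same index


def monthly_climatology(sst: SSTSeries) -> Climatology:
    """Per-calendar-month mean SST across all years of the record.

    Every calendar month must be represented at least once; otherwise the
    MMM could silently miss the warm season.
    """
    months = sst.dates.month
    means = []
    for m in range(1, 13):
        sel = sst.values[months == m]
        if sel.empty:
            raise ValidationError(f"no SST data for month: {calendar.month_name[m]}")
        means.append(float(sel.mean()))
    return Climatology(sst.location, tuple(means))


def hotspot_series(sst: SSTSeries, clim: Climatology) -> pd.Series:
    """Daily anomaly above the MMM (may be negative; negatives never accumulate)."""
    return sst.values - clim.mmm


def dhw_series(
    sst: SSTSeries,
    clim: Climatology,
    window_days: int = 84,
    hotspot_floor: float = 1.0,
) -> DHWSeries:
    """Degree heating weeks: trailing-window accumulation of HotSpots.

    dhw(t) = Σ_{s in trailing window_days} hotspot(s) / 7 over days where
    hotspot(s) ≥ hotspot_floor.  Units °C-weeks.  Days earlier than one
    full window into the record get a partial-window value, flagged via
    ``supported``.
    """
    if window_days <= 0:
        raise ParameterError(f"window_days must be positive, got {window_days}")
    if sst.gaps().size:
        raise ValidationError("SST series has calendar gaps; fill or split before DHW")
    hs = hotspot_series(sst, clim)
    contrib = hs.where(hs >= hotspot_floor, 0.0) / 7.0
    dhw = contrib.rolling(window=window_days, min_periods=1).sum()
    # Rolling sums of exact zeros can pick up float dust; clamp.
    dhw = dhw.clip(lower=0.0)
    supported = pd.Series(
        np.arange(len(dhw)) >= window_days - 1, index=dhw.index, name="supported"
    )
    return DHWSeries(sst.location, dhw.rename("dhw_cweeks"), supported)


def alert_level(
    dhw_value: float,
    bleaching_threshold: float = 4.0,
    mortality_threshold: float = 8.0,
) -> str:
    """Classify a DHW value against the bleaching/mortality risk thresholds.

    Thresholds are inclusive at their lower bound: exactly 4 °C-weeks is
    already bleaching-risk, exactly 8 °C-weeks mortality-risk.
    """
    if dhw_value < 0:
        raise ParameterError(f"DHW cannot be negative, got {dhw_value}")
    if dhw_value >= mortality_threshold:
        return ALERT_MORTALITY
    if dhw_value >= bleaching_threshold:
        return ALERT_BLEACHING
    return ALERT_NONE


# ----------------------------------------------------------------------
# File adapters


def read_sst(path: str | os.PathLike) -> list[SSTSeries]:
    """Read daily SST from CSV with columns (location, date, sst_c).

    Dates are ISO-8601.  Returns one series per location, in file order.
    """
    raw = pd.read_csv(path, comment="#")
    for col in ("location", "date", "sst_c"):
        if col not in raw.columns:
            raise FormatError(f"missing required column: {col}")
    out = []
    for loc in raw["location"].unique():
        sub = raw[raw["location"] == loc]
        idx = pd.to_datetime(sub["date"])
        values = pd.Series(sub["sst_c"].to_numpy(dtype=float), index=pd.DatetimeIndex(idx))
        out.append(SSTSeries(str(loc), values.sort_index()))
    return out


def write_dhw(
    sst: SSTSeries,
    dhw: DHWSeries,
    path: str | os.PathLike,
    bleaching_threshold: float = 4.0,
    mortality_threshold: float = 8.0,
) -> None:
    """Write SST + DHW + alert classification as CSV (mirrors the input layout)."""
    alerts = [
        alert_level(v, bleaching_threshold, mortality_threshold)
        for v in dhw.values.to_numpy()
    ]
    out = pd.DataFrame(
        {
            "location": sst.location,
            "date": sst.dates.strftime("%Y-%m-%d"),
            "sst_c": sst.values.to_numpy(),
            "dhw_cweeks": dhw.values.to_numpy(),
            "window_supported": dhw.supported.to_numpy(),
            "alert": alerts,
        }
    )
    out.to_csv(path, index=False)
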