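"""Exposure analytics on daily surface-NO₂ grids and series.

Holiday effects, weekday/weekend contrast, period-over-period relative
changes and recovery slopes, exceedance of the ambient standard, and the
urban–rural contrast.  All relative measures use the *reference* value
as denominator (rural mean, pre-period mean, baseline-year mean) and are
flagged undefined — never silently infinite — at zero references, since
near-zero levels inflate relative differences.

The weekend is Saturday+Sunday (the Chinese statutory weekend); holiday
calendars are supplied as date windows, with the 2019 Spring Festival
and National Day windows shipped as constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridField

__all__ = [
    "SPRING_FESTIVAL_2019",
    "NATIONAL_DAY_2019",
    "PeriodSpec",
    "moving_average",
    "relative_change",
    "holiday_effect",
    "weekday_weekend_diff",
    "trend_slope",
    "exceedance_fraction",
    "urban_rural_contrast",
]

NATIONAL_STANDARD_UGM3 = 80.0  # daily ambient NO2 standard

SPRING_FESTIVAL_2019 = ("2019-02-05", "2019-02-11")
NATIONAL_DAY_2019 = ("2019-10-01", "2019-10-07")


@dataclass(frozen=True)
class PeriodSpec:
    """Named, inclusive date windows (e.g. before/during/after a holiday)."""

    windows: Mapping[str, tuple[str, str]]

    def select(self, series: pd.Series, name: str) -> pd.Series:
        lo, hi = self.windows[name]
        out = series.loc[(series.index >= pd.Timestamp(lo)) & (series.index <= pd.Timestamp(hi))]
        if out.dropna().empty:
            raise ValueError(f"window {name!r} contains no valid day")
        return out.dropna()


def moving_average(series: pd.Series, window: int) -> pd.Series:
    """Centered moving mean; endpoints use the available partial window."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    return series.rolling(window, center=True, min_periods=1).mean()


def relative_change(value: float, reference: float) -> float:
    """Signed percent change of ``value`` against ``reference``.

    Raises at a zero reference rather than returning infinity.
    """
    if reference == 0:
        raise ZeroDivisionError("relative change undefined for a zero reference")
    return (value - reference) / reference * 100.0


def holiday_effect(
    daily: pd.Series,
    holiday: tuple[str, str],
    before: tuple[str, str],
    after: tuple[str, str],
) -> float:
    """Percent decline of the holiday mean against the surrounding baseline.

    The baseline pools the before- and after-window days; the sign is
    flipped so a decline is positive (an increase comes out negative).
    """
    spec = PeriodSpec({"holiday": holiday, "before": before, "after": after})
    during = spec.select(daily, "holiday")
    base = pd.concat([spec.select(daily, "before"), spec.select(daily, "after")])
    if during.index.intersection(base.index).size:
        raise ValueError("holiday and baseline windows overlap")
    return -relative_change(float(during.mean()), float(base.mean()))


def weekday_weekend_diff(daily: pd.Series) -> tuple[float, pd.Series]:
    """Mean(Mon–Fri) − mean(Sat–Sun) in data units, plus per-weekday means."""
    s = daily.dropna()
    dow = s.index.dayofweek
    weekday = s[dow < 5]
    weekend = s[dow >= 5]
    if weekday.empty or weekend.empty:
        raise ValueError("need at least one weekday and one weekend day")
    per_day = s.groupby(dow).mean()
    per_day.index = per_day.index.map(
        dict(enumerate(["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]))
    )
    return float(weekday.mean() - weekend.mean()), per_day


def trend_slope(daily: pd.Series) -> tuple[float, float]:
    """OLS slope (units/day) of a daily series, with two-sided p-value.

    The regressor is the day index counted from the first valid day.
    """
    s = daily.dropna()
    if len(s) < 3:
        raise ValueError("need at least 3 valid days")
    x = (s.index - s.index[0]).days.to_numpy(dtype=float)
    lr = stats.linregress(x, s.to_numpy(dtype=float))
    return float(lr.slope), float(lr.pvalue)


def exceedance_fraction(grid: GridField, threshold: float = NATIONAL_STANDARD_UGM3) -> np.ndarray:
    """Per-cell fraction of valid days whose value exceeds the threshold.

    Cells with no valid day are NaN.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    valid = ~grid.mask
    n_valid = valid.sum(axis=0).astype(float)
    n_exceed = ((grid.values > threshold) & valid).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_valid > 0, n_exceed / n_valid, np.nan)
    return frac


def urban_rural_contrast(annual: np.ndarray, urban_mask: np.ndarray) -> float:
    """Percent relative difference of the urban mean against the rural mean.

    ``annual`` is a 2-D mean field; ``urban_mask`` a boolean field of the
    same shape (urban segmentation is an input, not computed here).  NaN
    cells are ignored; both classes must be non-empty.
    """
    annual = np.asarray(annual, dtype=float)
    urban_mask = np.asarray(urban_mask, dtype=bool)
    if annual.shape != urban_mask.shape:
        raise ValueError("mask shape must match the field")
    valid = np.isfinite(annual)
    urban = annual[valid & urban_mask]
    rural = annual[valid & ~urban_mask]
    if urban.size == 0 or rural.size == 0:
        raise ValueError("urban and rural classes must both be non-empty")
    return relative_change(float(urban.mean()), float(rural.mean()))
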