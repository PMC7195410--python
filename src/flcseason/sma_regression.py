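"""Temperature-memory analysis by moving-average window scan.

For each candidate window length w (days), the simple moving average
(SMA) of daily temperature over the w days strictly preceding each
sampling date is regressed against the molecular response, and the window
maximising R² is reported as that variable's temperature-memory length.
The 1-day SMA is exactly the previous day's daily statistic; the 1-week
SMA averages the seven preceding days.

Responses are analysed on a log10 scale (mRNA series are already stored
log10; linear-scale ChIP levels are log-transformed here). The SMA itself
is log10-transformed only when every value in a window's scan is
positive — winter daily means can drop below 0 °C, in which case that
window's regression runs on the untransformed SMA and is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .timeseries_io import CoverageError, ReplicatedSeries, TemperatureSeries

logger = logging.getLogger("flcseason")

__all__ = ["SmaScanResult", "compute_sma", "scan_windows"]


@dataclass(frozen=True)
class SmaScanResult:
    """Window scan of a single response variable."""

    label: str
    windows: np.ndarray          # days, ascending, unique
    r2: np.ndarray               # in [0, 1], NaN where degenerate
    slope: np.ndarray
    intercept: np.ndarray
    transform_flag: np.ndarray   # True where the SMA entered untransformed
    statistic: str               # daily statistic used: mean | max | min

    @property
    def best_window(self) -> int:
        """Window attaining the maximum R² (ties -> smallest window)."""
        if np.all(np.isnan(self.r2)):
            raise ValueError(f"{self.label}: all regressions degenerate")
        return int(self.windows[np.nanargmax(self.r2)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.label,
            "window_days": self.windows,
            "r2": self.r2,
            "slope": self.slope,
            "intercept": self.intercept,
            "transform_flag": self.transform_flag,
        })


def compute_sma(
    temp: TemperatureSeries,
    window_days: int,
    at_dates: pd.DatetimeIndex,
    statistic: str = "mean",
) -> np.ndarray:
    """SMA of daily temperature over the window preceding each date.

    The temperature record is first aggregated to one value per calendar
    day by ``statistic`` (mean/max/min); the SMA at date d with window w
    is the mean of the daily values for days d-w .. d-1 (the day before
    the sampling date is day 1).
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    daily = temp.daily(statistic)
    # continuous daily axis so record gaps surface as NaN in the window
    full = daily.reindex(
        pd.date_range(daily.index[0], daily.index[-1], freq="D")
    )
    rolled = full.rolling(window=window_days).mean()
    at_dates = pd.DatetimeIndex(at_dates).normalize()
    out = rolled.reindex(at_dates - pd.Timedelta(days=1)).to_numpy()
    if np.any(np.isnan(out)):
        missing = [str(d.date()) for d, v in zip(at_dates, out)
                   if np.isnan(v)]
        raise CoverageError(
            f"window {window_days}d not covered before dates: {missing}"
        )
    return out


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R² of y on x; R² = 0 for a zero-variance response
    and NaN when the predictor is degenerate."""
    if np.ptp(x) == 0:
        return np.nan, np.nan, np.nan
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def scan_windows(
    response: ReplicatedSeries,
    temp: TemperatureSeries,
    windows: np.ndarray | list[int] | None = None,
    statistic: str = "mean",
) -> SmaScanResult:
    """OLS of the (log-scale) replicate-mean response on the SMA per window.

    Dates with no usable response value (all replicates missing, or a
    non-positive linear-scale value that cannot be log-transformed) are
    dropped pairwise. Requires at least 3 usable dates per window.
    """
    if windows is None:
        windows = np.arange(1, 169)
    windows = np.asarray(sorted(set(int(w) for w in windows)))
    mean = response.replicate_mean()

    if response.scale == "log10":
        y_all = mean
    else:
        y_all = np.where(mean > 0, np.log10(np.maximum(mean, 1e-300)), np.nan)
        n_dropped = int(np.sum(~np.isfinite(y_all) & np.isfinite(mean)))
        if n_dropped:
            logger.warning(
                "%s: %d non-positive values dropped before log transform",
                response.label, n_dropped,
            )

    r2 = np.full(len(windows), np.nan)
    slope = np.full(len(windows), np.nan)
    intercept = np.full(len(windows), np.nan)
    flag = np.zeros(len(windows), dtype=bool)

    for i, w in enumerate(windows):
        sma = compute_sma(temp, int(w), response.dates, statistic)
        ok = np.isfinite(y_all) & np.isfinite(sma)
        if ok.sum() < 3:
            raise ValueError(
                f"{response.label}: <3 usable dates at window {w}"
            )
        x = sma[ok]
        if np.all(x > 0):
            x = np.log10(x)
        else:
            flag[i] = True
            logger.info(
                "%s: window %dd SMA has non-positive values; regression on "
                "untransformed SMA", response.label, w,
            )
        slope[i], intercept[i], r2[i] = _ols(x, y_all[ok])

    return SmaScanResult(
        label=response.label, windows=windows, r2=r2, slope=slope,
        intercept=intercept, transform_flag=flag, statistic=statistic,
    )
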