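"""Phase relationships between paired seasonal series via Lissajous curves.

Two cyclical series, each min–max normalised within a year, are plotted
against one another; the closed trajectory (chronological order, last
point joined back to the first) forms a polygon whose signed area — by
the shoelace formula — quantifies the phase lag. With the earlier-varying
series on the horizontal axis, a delayed vertical-axis series traces the
curve clockwise (negative shoelace area under standard axes); for
sinusoids the |area| grows with the lag up to a quarter period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries_io import ReplicatedSeries

__all__ = ["LissajousResult", "normalise_yearly", "lissajous"]

#: |signed area| below which a trajectory is called degenerate (collinear)
DEGENERATE_AREA = 1e-6


@dataclass(frozen=True)
class LissajousResult:
    points: np.ndarray        # (n, 2), both coordinates in [0, 1]
    signed_area: float        # shoelace area; positive = anticlockwise
    orientation: str          # clockwise | anticlockwise | degenerate
    eccentricity: float       # ratio of principal-axis variances, in [0, 1]


def normalise_yearly(
    series: ReplicatedSeries,
    year_breaks: list | pd.DatetimeIndex | None = None,
) -> ReplicatedSeries:
    """Min–max normalise the replicate-mean series within each year.

    ``year_breaks`` are the dates starting each new segment (campaign
    anniversaries); by default one break per 365.25 days from the first
    sampling date. Each segment is affinely mapped so its minimum is 0 and
    maximum 1; a constant segment raises an error.
    """
    mean = series.replicate_mean()
    dates = series.dates
    if year_breaks is None:
        n_years = int(np.ceil(
            (dates[-1] - dates[0]).days / 365.25
        ))
        year_breaks = [dates[0] + pd.Timedelta(days=365.25 * k)
                       for k in range(1, n_years)]
    edges = [dates[0]] + list(pd.DatetimeIndex(year_breaks)) + [
        dates[-1] + pd.Timedelta(days=1)
    ]
    out = np.full_like(mean, np.nan)
    for lo, hi in zip(edges[:-1], edges[1:]):
        seg = (dates >= lo) & (dates < hi)
        if not seg.any():
            continue
        vals = mean[seg]
        finite = vals[np.isfinite(vals)]
        if len(finite) < 2 or np.ptp(finite) == 0:
            raise ValueError(
                f"{series.label}: segment ({lo.date()}, {hi.date()}] is "
                "constant or too short to normalise"
            )
        out[seg] = (vals - finite.min()) / np.ptp(finite)
    return ReplicatedSeries(
        dates=dates, values=out[:, None],
        label=series.label, scale="linear",
    )


def lissajous(x: ReplicatedSeries, y: ReplicatedSeries) -> LissajousResult:
    """Signed-area rotation statistic of the closed (x, y) trajectory.

    Both inputs must be normalised series on identical dates (>= 4
    points). The polygon through the chronologically ordered points,
    closed last-to-first, is measured by the shoelace formula; positive
    area means anticlockwise rotation. |area| is bounded by 1 on the unit
    square; values below 1e-6 are labelled degenerate.
    """
    if len(x.dates) != len(y.dates) or not (x.dates == y.dates).all():
        raise ValueError("x and y must share identical dates")
    xv = x.replicate_mean()
    yv = y.replicate_mean()
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    if len(xv) < 4:
        raise ValueError("need at least 4 points with both values present")
    area = 0.5 * float(
        np.sum(xv * np.roll(yv, -1) - np.roll(xv, -1) * yv)
    )
    if abs(area) < DEGENERATE_AREA:
        orientation = "degenerate"
    elif area > 0:
        orientation = "anticlockwise"
    else:
        orientation = "clockwise"
    pts = np.column_stack([xv, yv])
    centred = pts - pts.mean(axis=0)
    eigvals = np.linalg.eigvalsh(np.cov(centred.T))
    ecc = float(eigvals[0] / eigvals[1]) if eigvals[1] > 0 else 0.0
    return LissajousResult(
        points=pts, signed_area=area, orientation=orientation,
        eccentricity=ecc,
    )
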