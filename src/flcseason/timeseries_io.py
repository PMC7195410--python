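"""Dated-series containers, qPCR normalisation, and CSV round-trip I/O.

The two containers here are shared by every analysis stage:

* :class:`TemperatureSeries` — a high-frequency air-temperature record
  (10-minute to daily resolution) that can be aggregated to daily
  statistics or linearly interpolated to a continuous forcing ``T(t)``.
* :class:`ReplicatedSeries` — biweekly molecular observations (mRNA or one
  ChIP mark at one region) with a date × replicate matrix; missing cells
  are NaN, downstream analyses consume the replicate mean.

The canonical on-disk formats are plain CSV: ``timestamp,temp_c`` for
temperature and long-format ``date,label,replicate,value`` for
observations, both with ISO-8601 dates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("flcseason")

__all__ = [
    "TemperatureSeries",
    "ReplicatedSeries",
    "AnalysisConfig",
    "read_temperature",
    "write_temperature",
    "read_observations",
    "write_observations",
    "normalise_qpcr",
]

#: labels recognised as study variables; anything else is passed through
#: with a warning.
KNOWN_LABEL_PREFIXES = ("K27", "K4", "mRNA", "temp")


class FormatError(ValueError):
    """Unparseable or structurally invalid input file."""


class CoverageError(ValueError):
    """A requested date range is not covered by the temperature record."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemperatureSeries:
    """Air-temperature record with strictly increasing timestamps."""

    timestamps: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self):
        ts = pd.DatetimeIndex(self.timestamps)
        vals = np.asarray(self.values, dtype=float)
        if len(ts) != len(vals):
            raise ValueError("timestamps and values differ in length")
        if len(ts) < 2:
            raise ValueError("temperature series needs at least 2 points")
        if not ts.is_monotonic_increasing or ts.has_duplicates:
            dup = ts[ts.duplicated()]
            if len(dup):
                raise FormatError(f"duplicate timestamps: {list(dup[:3])}")
            raise FormatError("timestamps not strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ValueError("temperature values must be finite")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def start(self) -> pd.Timestamp:
        return self.timestamps[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.timestamps[-1]

    def daily(self, statistic: str = "mean") -> pd.Series:
        """Aggregate to one value per calendar day (mean/max/min)."""
        if statistic not in ("mean", "max", "min"):
            raise ValueError(f"unknown statistic {statistic!r}")
        s = pd.Series(self.values, index=self.timestamps)
        return getattr(s.groupby(s.index.normalize()), statistic)()

    def days_since_start(self) -> np.ndarray:
        """Time axis in days (float) relative to the first timestamp."""
        return (
            (self.timestamps - self.timestamps[0]).total_seconds().to_numpy()
            / 86400.0
        )

    def interpolator(self):
        """Piecewise-linear continuous forcing T(t), t in days from start.

        Constant extrapolation outside the record, mirroring the usual
        behaviour of interpolation helpers used for ODE forcing.
        """
        t = self.days_since_start()
        v = self.values

        def T(x):
            return np.interp(x, t, v)

        return T


@dataclass(frozen=True)
class ReplicatedSeries:
    """Dated observations with replicates (n_dates × n_replicates).

    ``scale`` records the unit convention: mRNA levels are stored on a
    common (base-10) logarithmic scale, ChIP levels on a linear scale.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    label: str
    scale: str = "linear"

    def __post_init__(self):
        dates = pd.DatetimeIndex(self.dates)
        vals = np.atleast_2d(np.asarray(self.values, dtype=float))
        if vals.shape[0] != len(dates):
            vals = vals.T
        if vals.shape[0] != len(dates):
            raise ValueError("values shape incompatible with dates")
        if not dates.is_monotonic_increasing or dates.has_duplicates:
            raise FormatError(f"{self.label}: dates not strictly increasing")
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "linear" and np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError(f"{self.label}: negative linear-scale value")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", vals)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def replicate_mean(self) -> np.ndarray:
        """Per-date mean over present replicates (NaN if none present)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=1)

    def replicate_sd(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanstd(self.values, axis=1, ddof=1)

    def with_values(self, values: np.ndarray) -> "ReplicatedSeries":
        return replace(self, values=values)


@dataclass
class AnalysisConfig:
    """All tunable knobs of the pipeline, with the study's defaults.

    Every stochastic stage carries its own seed so a whole analysis is a
    pure function of (data, config).
    """

    # moving-average scan
    sma_window_min: int = 1
    sma_window_max: int = 168
    # empirical dynamic modelling
    e_max: int = 24
    tp_min: int = -8
    tp_max: int = 4
    n_surrogates: int = 100
    convergence_threshold: float = 0.1
    n_library_sizes: int = 8
    n_library_draws: int = 100
    tp_tie_tolerance: float = 0.01
    spline_smoothing: float = 0.5
    # chromatin model thresholds (°C) and fitting
    theta1: float = 5.0
    theta2: float = 10.0
    theta3: float = 15.0
    theta4: float = 5.0
    param_upper_bound: float = 100.0
    n_random_draws: int = 1000
    # seeds, one per stochastic stage
    seed_synth: int = 10
    seed_ccm: int = 20
    seed_surrogate: int = 30
    seed_fit: int = 40

    def __post_init__(self):
        for name in (
            "sma_window_min", "sma_window_max", "e_max", "n_surrogates",
            "n_library_sizes", "n_library_draws", "n_random_draws",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("theta1", "theta2", "theta3", "theta4"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def thresholds(self) -> tuple[float, float, float, float]:
        return (self.theta1, self.theta2, self.theta3, self.theta4)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_temperature(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> TemperatureSeries:
    """Read a ``timestamp,temp_c`` CSV into a :class:`TemperatureSeries`.

    ``dialect`` maps the canonical column names (``timestamp``, ``value``)
    to the file's actual header names.
    """
    dialect = dict(dialect or {})
    ts_col = dialect.get("timestamp", "timestamp")
    val_col = dialect.get("value", "temp_c")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (ts_col, val_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    try:
        stamps = pd.to_datetime(df[ts_col], format="ISO8601")
    except (ValueError, TypeError):
        bad = None
        for i, raw in enumerate(df[ts_col]):
            try:
                pd.to_datetime(raw)
            except (ValueError, TypeError):
                bad = (i, raw)
                break
        if bad is not None:
            raise FormatError(
                f"{path}: unparseable timestamp {bad[1]!r} at row {bad[0] + 2}"
            ) from None
        stamps = pd.to_datetime(df[ts_col])
    order = np.argsort(stamps.to_numpy(), kind="stable")
    return TemperatureSeries(
        timestamps=pd.DatetimeIndex(stamps.to_numpy()[order]),
        values=df[val_col].to_numpy(dtype=float)[order],
    )


def write_temperature(series: TemperatureSeries, path: str | Path) -> None:
    pd.DataFrame({
        "timestamp": series.timestamps.astype(str),
        "temp_c": [np.format_float_positional(v, unique=True)
                   for v in series.values],
    }).to_csv(path, index=False)


def read_observations(path: str | Path) -> dict[str, ReplicatedSeries]:
    """Read a long-format ``date,label,replicate,value`` CSV.

    Returns one :class:`ReplicatedSeries` per label. Missing cells (empty
    value fields or absent rows) are preserved as NaN. mRNA labels are
    flagged log10-scale, everything else linear.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"date", "label", "replicate", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    df["date"] = pd.to_datetime(df["date"])
    out: dict[str, ReplicatedSeries] = {}
    for label, grp in df.groupby("label", sort=False):
        label = str(label)
        if not label.startswith(KNOWN_LABEL_PREFIXES):
            warnings.warn(f"unrecognised label {label!r}; passing through")
        wide = grp.pivot_table(
            index="date", columns="replicate", values="value", dropna=False
        ).sort_index()
        scale = "log10" if label.startswith("mRNA") else "linear"
        out[label] = ReplicatedSeries(
            dates=pd.DatetimeIndex(wide.index),
            values=wide.to_numpy(dtype=float),
            label=label,
            scale=scale,
        )
    return out


def write_observations(
    series: Iterable[ReplicatedSeries] | Mapping[str, ReplicatedSeries],
    path: str | Path,
) -> None:
    if isinstance(series, Mapping):
        series = list(series.values())
    rows = []
    for s in series:
        for i, date in enumerate(s.dates):
            for r in range(s.n_replicates):
                v = s.values[i, r]
                rows.append(
                    {
                        "date": date.date().isoformat(),
                        "label": s.label,
                        "replicate": r + 1,
                        "value": "" if np.isnan(v) else np.format_float_positional(
                            v, unique=True
                        ),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# qPCR normalisation
# ---------------------------------------------------------------------------

def normalise_qpcr(
    target_pct_input: float, h3_pct_input: float, control_locus: float
) -> float:
    """ChIP-qPCR normalisation: (target %input / H3 %input) / control locus.

    The target mark's percent-of-input is divided by the H3 percent-of-input
    at the same amplicon (nucleosome-occupancy correction), then by the same
    ratio at a control locus. Purely multiplicative, so invariant to any
    common rescaling of target and H3.
    """
    t = np.asarray(target_pct_input, dtype=float)
    h = np.asarray(h3_pct_input, dtype=float)
    c = np.asarray(control_locus, dtype=float)
    if np.any(t <= 0) or np.any(h <= 0) or np.any(c <= 0):
        raise ValueError("normalise_qpcr requires strictly positive inputs")
    out = (t / h) / c
    return float(out) if out.ndim == 0 else out
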