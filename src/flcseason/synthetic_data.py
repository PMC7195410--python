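"""Synthetic inputs with the statistical structure of the field study.

Three generators cover everything the pipeline consumes:

* :func:`gen_temperature` — a seasonal sinusoid (annual mean, amplitude,
  day-of-year of the minimum) plus AR(1)-correlated short-term
  fluctuations, at configurable sub-daily resolution. Defaults emulate a
  temperate lowland station record: 12 °C annual mean, 10 °C amplitude,
  coldest around late January, 2 °C short-term SD decaying over ~3 days.
* :func:`gen_observations` — model-generated chromatin/mRNA trajectories
  sampled on the biweekly campaign grid (2 years, 14-day interval, ~50
  dates, 4 replicates) with multiplicative log-normal observation noise.
* :func:`gen_coupled_logistic` — coupled logistic maps, the standard
  benchmark for validating cross-mapping causality detection.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatin_model import (
    ChromatinParams,
    ChromatinState,
    LogisticResponse,
    predict_mrna,
    scale_states_to_levels,
    simulate,
)
from .timeseries_io import ReplicatedSeries, TemperatureSeries

__all__ = [
    "TemperatureModel",
    "ObservationNoise",
    "gen_temperature",
    "gen_observations",
    "gen_coupled_logistic",
    "default_params",
    "default_maxima",
    "campaign_dates",
]


@dataclass(frozen=True)
class TemperatureModel:
    """Parameters of the synthetic seasonal temperature record."""

    annual_mean: float = 12.0        # °C
    amplitude: float = 10.0          # °C, half peak-to-trough
    phase: float = 25.0              # day of year of the minimum
    noise_sd: float = 2.0            # °C, stationary SD of fluctuations
    noise_decay_days: float = 3.0    # AR(1) autocorrelation e-folding time
    resolution: int = 1              # samples per day
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise SD must be >= 0")
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")


@dataclass(frozen=True)
class ObservationNoise:
    """Multiplicative log-normal observation noise per variable.

    ``sd`` values are SDs of the natural-log noise factor (so sd=0.1 is
    roughly 10% multiplicative noise). Defaults mirror the study design:
    4 biological replicates at 14-day intervals.
    """

    sd: dict = field(default_factory=lambda: {
        "K27_NR": 0.1, "K27_DNR": 0.1, "K4_NR": 0.1, "K4_DNR": 0.1,
        "mRNA": 0.1,
    })
    n_replicates: int = 4
    interval_days: int = 14
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.sd.values()):
            raise ValueError("noise SD must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")


def gen_temperature(
    model: TemperatureModel,
    n_years: int,
    start: str = "2012-03-26",
) -> TemperatureSeries:
    """Generate a seasonal temperature record spanning ``n_years`` years.

    Deterministic part: ``mean - amplitude*cos(2*pi*(doy - phase)/365.25)``
    so the annual minimum falls on day-of-year ``phase``. Fluctuations are
    a stationary AR(1) process with the configured SD and e-folding decay.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(model.seed)
    n = int(round(n_years * 365.25 * model.resolution)) + 1
    step_days = 1.0 / model.resolution
    stamps = pd.date_range(
        start=start, periods=n, freq=pd.Timedelta(days=step_days)
    )
    doy = stamps.dayofyear.to_numpy() + (
        stamps.hour.to_numpy() + stamps.minute.to_numpy() / 60.0
    ) / 24.0
    seasonal = model.annual_mean - model.amplitude * np.cos(
        2 * np.pi * (doy - model.phase) / 365.25
    )
    if model.noise_sd > 0:
        rho = np.exp(-step_days / model.noise_decay_days)
        innov_sd = model.noise_sd * np.sqrt(1 - rho**2)
        eps = rng.normal(0.0, innov_sd, size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, model.noise_sd)
        for i in range(1, n):
            noise[i] = rho * noise[i - 1] + eps[i]
    else:
        noise = np.zeros(n)
    return TemperatureSeries(timestamps=stamps, values=seasonal + noise)


def campaign_dates(
    temp: TemperatureSeries,
    interval_days: int = 14,
    n_years: float = 2.0,
    start_offset_days: float = 183.0,
) -> pd.DatetimeIndex:
    """Biweekly sampling dates covering ``n_years`` within the record."""
    start = temp.start + pd.Timedelta(days=start_offset_days)
    n_points = int(np.floor(n_years * 365.25 / interval_days)) + 1
    dates = pd.date_range(start=start, periods=n_points,
                          freq=pd.Timedelta(days=interval_days))
    if dates[-1] > temp.end:
        raise ValueError(
            f"temperature record ends {temp.end}, before the last "
            f"sampling date {dates[-1]}"
        )
    return dates


def default_params(variant: int = 1) -> ChromatinParams:
    """Reference parameter set producing study-like seasonal dynamics.

    Rates are per day; thermosensor thresholds are the fixed 5/10/15/5 °C.
    Chosen so that, under the default temperature model, K27 at the NR
    nucleates over the winter months, spreads to the DNR with a delay
    driven by intermittent warm episodes, and is removed in spring with
    K4 feedback; K4 at the DNR appears transiently in cold.
    """
    return ChromatinParams(
        mu=LogisticResponse(0.24, 0.33, 5.0, "cold-activated"),
        nu=LogisticResponse(0.11, 1.1, 10.0, "warm-activated"),
        xi=LogisticResponse(0.46, 0.26, 15.0, "warm-activated"),
        tau_fn=LogisticResponse(0.14, 0.34, 5.0, "cold-activated"),
        kappa=0.10,
        lam=0.26,
        phi=0.20,
        psi=0.29,
        variant=variant,
        sigma=1.2,
        omega=-0.5,
    )


def default_maxima() -> dict[str, float]:
    """Observation scales: two-year maximum level per region-level series."""
    return {"K27_NR": 2.0, "K27_DNR": 1.5, "K4_NR": 3.0, "K4_DNR": 1.0}


DEFAULT_INIT = ChromatinState(
    uNuD=0.81, mNuD=0.09, mNmD=0.01, uNmD=0.09, aN=0.9, aD=0.05
)


def gen_observations(
    params: ChromatinParams,
    temp: TemperatureSeries,
    noise: ObservationNoise,
    maxima: dict[str, float] | None = None,
    init: ChromatinState = DEFAULT_INIT,
    n_years: float = 2.0,
    start_offset_days: float = 183.0,
) -> dict[str, ReplicatedSeries]:
    """Model-generated biweekly observations with replicate noise.

    The deterministic model is integrated over the temperature record,
    sampled at the biweekly campaign dates, converted from state
    proportions to levels via ``maxima``, and the mRNA series derived from
    the K4 level at the NR through the log-log link. Each replicate is the
    deterministic value times an independent log-normal factor (applied on
    the linear scale; for mRNA this is additive on the log10 scale).
    """
    maxima = dict(maxima or default_maxima())
    dates = campaign_dates(temp, noise.interval_days, n_years,
                           start_offset_days)
    t_grid = (dates - temp.start).total_seconds().to_numpy() / 86400.0
    traj = simulate(params, temp, t_grid, init)
    levels = scale_states_to_levels(traj, maxima)
    # guard against exact zeros before the log-log mRNA link
    k4 = np.maximum(levels["K4_NR"], 1e-12)
    log_mrna = predict_mrna(k4, params.sigma, params.omega)

    rng = np.random.default_rng(noise.seed)
    out: dict[str, ReplicatedSeries] = {}
    for label, truth in levels.items():
        sd = noise.sd.get(label, 0.0)
        factors = np.exp(rng.normal(0.0, sd,
                                    size=(len(truth), noise.n_replicates)))
        out[label] = ReplicatedSeries(
            dates=dates, values=truth[:, None] * factors,
            label=label, scale="linear",
        )
    sd = noise.sd.get("mRNA", 0.0)
    factors = np.exp(rng.normal(0.0, sd,
                                size=(len(log_mrna), noise.n_replicates)))
    out["mRNA"] = ReplicatedSeries(
        dates=dates,
        values=log_mrna[:, None] + np.log10(factors),
        label="mRNA", scale="log10",
    )
    return out


def gen_coupled_logistic(
    r_x: float,
    r_y: float,
    beta_xy: float,
    beta_yx: float,
    n: int,
    seed: int,
    n_discard: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Coupled logistic maps, the canonical cross-mapping benchmark.

        x[t+1] = x[t] * (r_x - r_x*x[t] - beta_xy*y[t])
        y[t+1] = y[t] * (r_y - r_y*y[t] - beta_yx*x[t])

    ``beta_xy`` is the forcing of y on x (so with ``beta_xy > 0`` and
    ``beta_yx = 0``, y drives x and cross-mapping from x's reconstruction
    should recover y). Initial states are drawn from (0.2, 0.8); a
    transient of ``n_discard`` steps is discarded. Trajectories escaping
    (0, 1) raise a rejection error.
    """
    if n < 50:
        raise ValueError("n must be >= 50")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.2, 0.8)
    y = rng.uniform(0.2, 0.8)
    xs = np.empty(n)
    ys = np.empty(n)
    for t in range(n_discard + n):
        x, y = (
            x * (r_x - r_x * x - beta_xy * y),
            y * (r_y - r_y * y - beta_yx * x),
        )
        if not (0.0 < x < 1.0 and 0.0 < y < 1.0):
            raise ValueError(
                "trajectory escaped (0,1); lower the growth rates or "
                "coupling strengths"
            )
        if t >= n_discard:
            xs[t - n_discard] = x
            ys[t - n_discard] = y
    return xs, ys
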