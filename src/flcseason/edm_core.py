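"""Empirical dynamic modelling: simplex projection and cross-mapping.

Equation-free causality analysis for short seasonal time series, built on
attractor reconstruction by delay embedding (Takens). The pieces are:

* :func:`embed` — lagged-coordinate reconstruction of a scalar series;
* :func:`simplex_forecast` — leave-one-out nearest-neighbour forecasting
  with E+1 neighbours and exponential distance weighting, used by
  :func:`select_embedding` to pick the embedding dimension by minimum
  prediction RMSE over E = 1..24;
* :func:`ccm` — convergent cross-mapping: the delay embedding of a
  putative *effect* variable is used to predict a putative *cause*; skill
  (Pearson rho) that rises with library size indicates that the cause has
  left its signature in the effect's dynamics;
* :func:`seasonal_surrogates` — null series preserving the seasonal mean
  profile while permuting anomalies within years, guarding against
  seasonality-driven spurious causality;
* :func:`detect_causality` — the full two-criterion verdict per
  direction: scan time-to-prediction tp over a configured range (negative
  best tp = cause precedes effect), then require the observed skill at
  the maximum library size to exceed the surrogate 95% bound and the
  skill to converge (final-minus-initial library skill > 0.1).

All forecasts share one convention: an embedding row built from values at
times t, t-tau, .., t-(E-1)tau predicts the target series at time t + tp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.spatial.distance import cdist

from .timeseries_io import AnalysisConfig, TemperatureSeries

__all__ = [
    "EmbeddingSpec",
    "SimplexResult",
    "CCMResult",
    "standardise",
    "smooth_temperature",
    "embed",
    "simplex_forecast",
    "select_embedding",
    "ccm",
    "seasonal_surrogates",
    "detect_causality",
]


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters: dimension E, lag tau (in sampling
    steps; one step = one sampling interval, 2 weeks in the study design),
    and time-to-prediction tp."""

    E: int
    tau: int = 1
    tp: int = 1

    def __post_init__(self):
        if self.E < 1:
            raise ValueError("E must be >= 1")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")


@dataclass(frozen=True)
class SimplexResult:
    """Univariate forecast-skill scan over embedding dimension."""

    E_values: np.ndarray
    rho: np.ndarray          # Pearson skill per E (NaN if degenerate)
    rmse: np.ndarray         # prediction RMSE per E

    @property
    def best_E(self) -> int:
        """E attaining minimum RMSE (ties -> smallest E)."""
        return int(self.E_values[np.nanargmin(self.rmse)])


@dataclass(frozen=True)
class CCMResult:
    """One cross-mapping direction with its causality verdict.

    ``direction`` reads "A xmap B": the state of B is predicted from A's
    delay embedding, measuring the effect of B on A.
    """

    direction: str
    tps: np.ndarray
    rho_by_tp: np.ndarray          # skill per tp at the maximum library
    surrogate_q95: np.ndarray      # 95th surrogate percentile per tp
    best_tp: int
    library_sizes: np.ndarray      # ascending
    rho_by_library: np.ndarray     # draw-averaged skill per size at best_tp
    convergence_delta: float       # rho(final library) - rho(initial)
    rho_max: float                 # skill at max library at best_tp
    verdict: bool                  # causal per the two-criterion test

    def summary(self) -> dict:
        return {
            "direction": self.direction,
            "best_tp": self.best_tp,
            "rho_max": self.rho_max,
            "surrogate_q95": float(
                self.surrogate_q95[list(self.tps).index(self.best_tp)]
            ),
            "convergence_delta": self.convergence_delta,
            "verdict": "causal" if self.verdict else "not causal",
        }


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------

def standardise(values: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-SD (sample SD, n-1 denominator) transform."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardise a zero-variance series")
    return (x - x.mean()) / sd


def smooth_temperature(
    temp: TemperatureSeries, smoothing: float = 0.5
) -> TemperatureSeries:
    """Smoothing-spline fit to the daily mean temperature.

    ``smoothing`` in [0, 1] dials the penalty of a cubic smoothing spline
    on the daily means: near 0 the fit approaches interpolation, near 1 it
    approaches the least-squares line. Internally the day axis is scaled
    to [0, 1] and the roughness penalty is ``n**-1.5 * 256**(3s-1)`` —
    the same log-256 ladder used by classical spline-smoothness dials —
    which at s = 0.5 removes day-scale fluctuations while preserving the
    seasonal cycle.
    """
    if not 0 <= smoothing <= 1:
        raise ValueError("smoothing must be in [0, 1]")
    daily = temp.daily("mean")
    if len(daily) < 10:
        raise ValueError("need >= 10 daily values to smooth")
    x_days = (daily.index - daily.index[0]).days.to_numpy(dtype=float)
    x = x_days / x_days[-1]
    y = daily.to_numpy()
    if smoothing >= 1.0:
        coef = np.polyfit(x, y, 1)
        smoothed = np.polyval(coef, x)
    else:
        lam = len(x) ** -1.5 * 256.0 ** (3.0 * smoothing - 1.0)
        spline = make_smoothing_spline(x, y, lam=lam)
        smoothed = spline(x)
    return TemperatureSeries(
        timestamps=pd.DatetimeIndex(daily.index), values=smoothed
    )


# ---------------------------------------------------------------------------
# delay embedding and simplex projection
# ---------------------------------------------------------------------------

def embed(series: np.ndarray, spec: EmbeddingSpec) -> np.ndarray:
    """Delay-coordinate matrix: row i = (x_t, x_{t-tau}, ..,
    x_{t-(E-1)tau}) with t = (E-1)*tau + i; shape (n-(E-1)*tau, E)."""
    x = np.asarray(series, dtype=float)
    offset = (spec.E - 1) * spec.tau
    if len(x) <= offset:
        raise ValueError(
            f"series of length {len(x)} too short for E={spec.E}, "
            f"tau={spec.tau}"
        )
    cols = [x[offset - k * spec.tau: len(x) - k * spec.tau]
            for k in range(spec.E)]
    return np.column_stack(cols)


class _CrossMap:
    """Shared machinery: embed an effect series once, then predict any
    target series at any tp from any neighbour library."""

    def __init__(self, series: np.ndarray, E: int, tau: int):
        self.x = np.asarray(series, dtype=float)
        self.n = len(self.x)
        self.E = E
        self.tau = tau
        self.offset = (E - 1) * tau
        self.block = embed(self.x, EmbeddingSpec(E, tau))
        self.times = np.arange(self.offset, self.n)  # time of each row
        self.dist = cdist(self.block, self.block)
        np.fill_diagonal(self.dist, np.inf)  # leave-one-out

    def valid_rows(self, tp: int) -> np.ndarray:
        """Rows whose prediction target (time + tp) is inside the series."""
        t = self.times + tp
        return np.nonzero((t >= 0) & (t < self.n))[0]

    def neighbours(self, tp: int, library: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """E+1 nearest library neighbours and simplex weights per query.

        ``library`` is a row-index array (default: all rows valid at this
        tp). Queries are all rows valid at tp. Returns (query_rows,
        neighbour row indices (n_q, E+1), weights (n_q, E+1)).
        """
        queries = self.valid_rows(tp)
        library = queries if library is None else np.asarray(library)
        k = self.E + 1
        if len(library) < k + 1:
            raise ValueError(
                f"library of {len(library)} too small for E+1="
                f"{k} neighbours"
            )
        sub = self.dist[np.ix_(queries, library)]
        part = np.argpartition(sub, k - 1, axis=1)[:, :k]
        rows = np.arange(len(queries))[:, None]
        d = sub[rows, part]
        order = np.argsort(d, axis=1)
        d = d[rows, order]
        nbr = library[part[rows, order]]
        d_min = d[:, :1]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.exp(-d / d_min)
        # exact matches: uniform weight over zero-distance neighbours
        zero_min = (d_min[:, 0] == 0)
        if np.any(zero_min):
            w[zero_min] = (d[zero_min] == 0).astype(float)
        w /= w.sum(axis=1, keepdims=True)
        return queries, nbr, w

    def predict(self, target: np.ndarray, tp: int,
                queries: np.ndarray, nbr: np.ndarray, w: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
        """Cross-map predictions and observations of ``target`` at tp."""
        y = np.asarray(target, dtype=float)
        pred = (w * y[self.times[nbr] + tp]).sum(axis=1)
        obs = y[self.times[queries] + tp]
        return pred, obs


def _skill(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    """(rho, rmse); rho is NaN when either side has zero variance."""
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.std(pred) == 0 or np.std(obs) == 0:
        return np.nan, rmse
    return float(np.corrcoef(pred, obs)[0, 1]), rmse


def simplex_forecast(
    series: np.ndarray, spec: EmbeddingSpec
) -> tuple[float, float]:
    """Leave-one-out univariate simplex projection: (rho, RMSE).

    Each embedded point predicts its own series ``tp`` steps ahead from
    its E+1 nearest neighbours (self excluded), weighted by
    exp(-d/d_min).
    """
    cm = _CrossMap(series, spec.E, spec.tau)
    queries, nbr, w = cm.neighbours(spec.tp)
    pred, obs = cm.predict(cm.x, spec.tp, queries, nbr, w)
    return _skill(pred, obs)


def select_embedding(
    series: np.ndarray,
    e_max: int = 24,
    tau: int = 1,
    tp: int = 1,
) -> SimplexResult:
    """Scan E = 1..e_max; best E minimises forecast RMSE (ties -> smallest).

    E values infeasible for the series length (too few embedded points to
    supply E+1 neighbours) are skipped.
    """
    E_values, rhos, rmses = [], [], []
    for E in range(1, e_max + 1):
        try:
            rho, rmse = simplex_forecast(series, EmbeddingSpec(E, tau, tp))
        except ValueError:
            continue
        E_values.append(E)
        rhos.append(rho)
        rmses.append(rmse)
    if not E_values:
        raise ValueError("no feasible embedding dimension for this length")
    return SimplexResult(
        E_values=np.array(E_values), rho=np.array(rhos),
        rmse=np.array(rmses),
    )


# ---------------------------------------------------------------------------
# convergent cross-mapping
# ---------------------------------------------------------------------------

def _library_grid(n_available: int, E: int, n_sizes: int) -> np.ndarray:
    """Ascending library sizes from E+2 to all available points."""
    lo = E + 2
    hi = n_available
    if hi <= lo:
        raise ValueError("too few points for a library-size scan")
    return np.unique(np.linspace(lo, hi, n_sizes).round().astype(int))


def ccm(
    effect_recon: np.ndarray,
    cause: np.ndarray,
    spec: EmbeddingSpec,
    library_sizes: np.ndarray,
    n_draws: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Cross-map skill per library size (averaged over random libraries).

    The effect variable's reconstruction predicts the cause at lag
    ``spec.tp``; for each library size L, ``n_draws`` random L-point
    libraries are drawn (without replacement) from the embedded points
    and the resulting Pearson skills averaged.
    """
    x = np.asarray(effect_recon, float)
    y = np.asarray(cause, float)
    if len(x) != len(y):
        raise ValueError("effect and cause series must have equal length")
    cm = _CrossMap(x, spec.E, spec.tau)
    candidates = cm.valid_rows(spec.tp)
    library_sizes = np.asarray(library_sizes, int)
    if np.any(library_sizes < spec.E + 2):
        raise ValueError(f"library sizes below E+2={spec.E + 2}")
    if np.any(library_sizes > len(candidates)):
        raise ValueError(
            f"library sizes exceed the {len(candidates)} available points"
        )
    rng = np.random.default_rng(seed)
    out = np.empty(len(library_sizes))
    for li, L in enumerate(library_sizes):
        skills = []
        for _ in range(n_draws if L < len(candidates) else 1):
            lib = rng.choice(candidates, size=L, replace=False)
            queries, nbr, w = cm.neighbours(spec.tp, lib)
            pred, obs = cm.predict(y, spec.tp, queries, nbr, w)
            rho, _ = _skill(pred, obs)
            skills.append(rho)
        out[li] = np.nanmean(skills)
    return out


def seasonal_surrogates(
    series: np.ndarray,
    dates: pd.DatetimeIndex,
    n: int,
    seed: int,
) -> np.ndarray:
    """Null series preserving the seasonal profile, shape (n, len(series)).

    The seasonal mean profile is estimated by position in the annual
    sampling cycle (averaging across years); each surrogate adds a random
    within-year permutation of the residuals back onto the profile, so
    seasonality is retained while shorter-scale structure is destroyed.
    """
    x = np.asarray(series, dtype=float)
    dates = pd.DatetimeIndex(dates)
    span_days = (dates[-1] - dates[0]).days
    if span_days < 365:
        raise ValueError("seasonal surrogates need >= 1 full annual cycle")
    interval = np.median(np.diff(dates.to_numpy()).astype(
        "timedelta64[s]").astype(float)) / 86400.0
    per_year = int(round(365.25 / interval))
    pos = np.arange(len(x)) % per_year
    year = np.arange(len(x)) // per_year
    profile = np.array([
        x[pos == p].mean() if np.any(pos == p) else np.nan
        for p in range(per_year)
    ])
    resid = x - profile[pos]
    rng = np.random.default_rng(seed)
    out = np.empty((n, len(x)))
    for s in range(n):
        perm = np.empty_like(resid)
        for yr in np.unique(year):
            sel = np.nonzero(year == yr)[0]
            perm[sel] = resid[rng.permutation(sel)]
        out[s] = profile[pos] + perm
    return out


def _permutation_surrogates(series, n, seed):
    rng = np.random.default_rng(seed)
    x = np.asarray(series, float)
    return np.array([rng.permutation(x) for _ in range(n)])


def _one_direction(
    effect: np.ndarray,
    cause: np.ndarray,
    label: str,
    E: int,
    config: AnalysisConfig,
    dates: pd.DatetimeIndex | None,
) -> CCMResult:
    cm = _CrossMap(effect, E, tau=1)
    tps = np.arange(config.tp_min, config.tp_max + 1)

    # skill per tp at the full (maximum) library
    rho_by_tp = np.empty(len(tps))
    nbr_cache = {}
    for i, tp in enumerate(tps):
        queries, nbr, w = cm.neighbours(int(tp))
        nbr_cache[int(tp)] = (queries, nbr, w)
        pred, obs = cm.predict(cause, int(tp), queries, nbr, w)
        rho_by_tp[i], _ = _skill(pred, obs)

    # best tp by maximum skill; skills within a small tolerance of the
    # maximum (far below the sampling error of a correlation at these
    # series lengths) count as tied, resolved toward the tp closest to 0 —
    # the weakest causal-delay claim
    best = np.nanmax(rho_by_tp)
    tied = tps[rho_by_tp >= best - config.tp_tie_tolerance]
    best_tp = int(tied[np.argmin(np.abs(tied))])
    rho_max = float(rho_by_tp[list(tps).index(best_tp)])

    # surrogate envelope per tp, cross-mapping onto surrogate causes at
    # the full library (neighbour structure is fixed by the effect's
    # embedding, so only predictions are recomputed)
    if dates is not None:
        sur = seasonal_surrogates(
            cause, dates, config.n_surrogates, config.seed_surrogate
        )
    else:
        sur = _permutation_surrogates(
            cause, config.n_surrogates, config.seed_surrogate
        )
    sur_q95 = np.empty(len(tps))
    for i, tp in enumerate(tps):
        queries, nbr, w = cm.neighbours(int(tp))
        skills = np.empty(len(sur))
        for s, ysur in enumerate(sur):
            pred, obs = cm.predict(ysur, int(tp), queries, nbr, w)
            skills[s], _ = _skill(pred, obs)
        sur_q95[i] = np.nanpercentile(skills, 95)

    # convergence over library size at the best tp
    candidates = cm.valid_rows(best_tp)
    sizes = _library_grid(len(candidates), E, config.n_library_sizes)
    rho_by_library = ccm(
        effect, cause, EmbeddingSpec(E, 1, best_tp), sizes,
        n_draws=config.n_library_draws, seed=config.seed_ccm,
    )
    delta = float(rho_by_library[-1] - rho_by_library[0])

    verdict = (
        best_tp <= 0
        and rho_max > sur_q95[list(tps).index(best_tp)]
        and delta > config.convergence_threshold
    )
    return CCMResult(
        direction=label, tps=tps, rho_by_tp=rho_by_tp,
        surrogate_q95=sur_q95, best_tp=best_tp,
        library_sizes=sizes, rho_by_library=rho_by_library,
        convergence_delta=delta, rho_max=rho_max, verdict=bool(verdict),
    )


def detect_causality(
    a: np.ndarray,
    b: np.ndarray,
    config: AnalysisConfig | None = None,
    dates: pd.DatetimeIndex | None = None,
    labels: tuple[str, str] = ("A", "B"),
    E_a: int | None = None,
    E_b: int | None = None,
) -> dict[str, CCMResult]:
    """Two-direction cross-mapping causality test between series a and b.

    Series are standardised internally. Embedding dimensions default to
    the minimum-RMSE simplex choice per reconstructed (effect) variable.
    With ``dates`` given, the null envelope uses seasonal surrogates;
    without dates (e.g. map benchmarks) it uses random permutations of
    the cause series.

    Returns ``{"A xmap B": ..., "B xmap A": ...}`` (with the supplied
    labels); "A xmap B" predicts B from A's reconstruction and therefore
    tests whether B causally forces A.
    """
    config = config or AnalysisConfig()
    a = standardise(a)
    b = standardise(b)
    la, lb = labels
    e_cap = min(config.e_max, (len(a) - 4) // 2)
    if E_a is None:
        E_a = select_embedding(a, e_max=e_cap).best_E
    if E_b is None:
        E_b = select_embedding(b, e_max=e_cap).best_E
    return {
        f"{la} xmap {lb}": _one_direction(
            a, b, f"{la} xmap {lb}", E_a, config, dates),
        f"{lb} xmap {la}": _one_direction(
            b, a, f"{lb} xmap {la}", E_b, config, dates),
    }
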