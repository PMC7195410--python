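"""Temperature-forced model of FLC chromatin states.

A single FLC locus carries a joint H3K27me3 state over the nucleation
region (NR) and the distal nucleation region (DNR), cycling
unidirectionally through four states::

    UU --mu(T)--> MU --nu(T)--> MM --kappa*aN--> UM --lambda--> UU

where ``mu`` fires in cold (the vernalising nucleation step) and ``nu``
during warm episodes (spreading to the DNR). H3K4me3 (active-mark)
occupancy at each region follows a balance equation with its own
thermosensor — warm-activated at the NR (``xi``) and cold-activated at the
DNR (``tau``) — and three feedback couplings between the marks:

* K4 at the NR drives the K27 removal step MM -> UM (rate ``kappa * aN``);
* K27 covering the NR (mNuD + mNmD) represses K4 at the NR (``phi``);
* K27 covering the DNR (mNmD + uNmD) represses K4 at the DNR (``psi``).

Tissue-level observables are the proportions of loci in each state. With
``uN = 1 - aN`` and ``uD = 1 - aD`` the K4-unmodified proportions, the
deterministic equations are

    d(uNuD)/dt = lambda*uNmD      - mu(T)*uNuD
    d(mNuD)/dt = mu(T)*uNuD       - nu(T)*mNuD
    d(mNmD)/dt = nu(T)*mNuD       - kappa*aN*mNmD
    d(uNmD)/dt = kappa*aN*mNmD    - lambda*uNmD
    d(aN)/dt   = xi(T)*(1-aD)*uN  - phi*(mNuD+mNmD)*aN
    d(aD)/dt   = tau(T)*(1-aN)*uD - psi*(mNmD+uNmD)*aD

Model variants drop one feedback each: variant 2 replaces ``kappa*aN`` by
``kappa``, variant 3 replaces ``phi*(mNuD+mNmD)`` by ``phi``, and variant
4 replaces ``psi*(mNmD+uNmD)`` by ``psi``.

A stochastic per-locus counterpart (finite population of loci, discrete
states, time-inhomogeneous jump rates) is provided by
:func:`simulate_stochastic`; its ensemble mean converges to the ODE
solution as the number of loci grows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numba
import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .timeseries_io import TemperatureSeries

__all__ = [
    "LogisticResponse",
    "ChromatinParams",
    "ChromatinState",
    "logistic_rate",
    "ode_rhs",
    "apply_variant",
    "simulate",
    "simulate_stochastic",
    "find_fixed_point",
    "predict_mrna",
    "scale_states_to_levels",
    "initial_state_from_levels",
]

#: default threshold temperatures (°C) of the four thermosensors
DEFAULT_THRESHOLDS = (5.0, 10.0, 15.0, 5.0)

#: hard upper bound on all rate/steepness parameters (per day, per °C)
PARAM_UPPER_BOUND = 100.0

STATE_NAMES = ("uNuD", "mNuD", "mNmD", "uNmD", "aN", "aD")


# ---------------------------------------------------------------------------
# thermosensors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticResponse:
    """Logistic map from temperature to a transition rate (per day).

    ``cold-activated``: rate -> amplitude as T -> -inf and -> 0 as
    T -> +inf; ``warm-activated`` is the mirror image. At T == threshold
    the rate is amplitude/2 in either direction.
    """

    amplitude: float
    steepness: float
    threshold: float
    direction: Literal["cold-activated", "warm-activated"]

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0")
        if self.direction not in ("cold-activated", "warm-activated"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def __call__(self, T):
        return logistic_rate(T, self)


def logistic_rate(T, f: LogisticResponse):
    """Evaluate a thermosensor at temperature ``T`` (°C, scalar or array)."""
    sign = 1.0 if f.direction == "cold-activated" else -1.0
    z = np.clip(sign * f.steepness * (np.asarray(T, float) - f.threshold),
                -500, 500)
    return f.amplitude / (1.0 + np.exp(z))


# ---------------------------------------------------------------------------
# parameters and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromatinParams:
    """All rates of the chromatin model plus the mRNA link.

    Parameter symbols follow the field convention: ``zeta/alpha/theta1``
    for the cold-activated nucleation sensor mu(T); ``eta/beta/theta2``
    for the warm-activated spreading sensor nu(T); ``iota/gamma/theta3``
    for the warm-activated K4-NR sensor xi(T); ``rho_amp/epsilon/theta4``
    for the cold-activated K4-DNR sensor tau(T). ``sigma``/``omega`` are
    the slope and intercept of the log-log mRNA regression on K4 at the NR.
    """

    mu: LogisticResponse
    nu: LogisticResponse
    xi: LogisticResponse
    tau_fn: LogisticResponse
    kappa: float
    lam: float
    phi: float
    psi: float
    variant: int = 1
    sigma: float = 1.0
    omega: float = 0.0

    def __post_init__(self):
        for name in ("kappa", "lam", "phi", "psi"):
            v = getattr(self, name)
            if not 0 <= v <= PARAM_UPPER_BOUND:
                raise ValueError(f"{name}={v} outside [0, {PARAM_UPPER_BOUND}]")
        for sensor in (self.mu, self.nu, self.xi, self.tau_fn):
            if sensor.amplitude > PARAM_UPPER_BOUND:
                raise ValueError("thermosensor amplitude above upper bound")
        if self.variant not in (1, 2, 3, 4):
            raise ValueError(f"unknown variant {self.variant}")

    def with_variant(self, variant: int) -> "ChromatinParams":
        return replace(self, variant=variant)

    # -- flat-key (de)serialisation used by the CLI and the fitter --------

    @classmethod
    def from_dict(cls, d: dict) -> "ChromatinParams":
        th1 = d.get("theta1", DEFAULT_THRESHOLDS[0])
        th2 = d.get("theta2", DEFAULT_THRESHOLDS[1])
        th3 = d.get("theta3", DEFAULT_THRESHOLDS[2])
        th4 = d.get("theta4", DEFAULT_THRESHOLDS[3])
        return cls(
            mu=LogisticResponse(d["zeta"], d["alpha"], th1, "cold-activated"),
            nu=LogisticResponse(d["eta"], d["beta"], th2, "warm-activated"),
            xi=LogisticResponse(d["iota"], d["gamma"], th3, "warm-activated"),
            tau_fn=LogisticResponse(d["rho_amp"], d["epsilon"], th4,
                                    "cold-activated"),
            kappa=d["kappa"],
            lam=d["lambda"],
            phi=d["phi"],
            psi=d["psi"],
            variant=int(d.get("variant", 1)),
            sigma=d.get("sigma", 1.0),
            omega=d.get("omega", 0.0),
        )

    def to_dict(self) -> dict:
        return {k: (int(v) if k == "variant" else float(v))
                for k, v in self._raw_dict().items()}

    def _raw_dict(self) -> dict:
        return {
            "zeta": self.mu.amplitude, "alpha": self.mu.steepness,
            "theta1": self.mu.threshold,
            "eta": self.nu.amplitude, "beta": self.nu.steepness,
            "theta2": self.nu.threshold,
            "iota": self.xi.amplitude, "gamma": self.xi.steepness,
            "theta3": self.xi.threshold,
            "rho_amp": self.tau_fn.amplitude, "epsilon": self.tau_fn.steepness,
            "theta4": self.tau_fn.threshold,
            "kappa": self.kappa, "lambda": self.lam,
            "phi": self.phi, "psi": self.psi,
            "variant": self.variant,
            "sigma": self.sigma, "omega": self.omega,
        }


@dataclass(frozen=True)
class ChromatinState:
    """Six model proportions: four joint K27 states + two K4 occupancies."""

    uNuD: float
    mNuD: float
    mNmD: float
    uNmD: float
    aN: float
    aD: float

    def __post_init__(self):
        vec = self.as_array()
        if np.any(vec < -1e-9) or np.any(vec > 1 + 1e-9):
            raise ValueError(f"state outside [0,1]: {vec}")
        if abs(vec[:4].sum() - 1.0) > 1e-9:
            raise ValueError(f"K27 proportions sum to {vec[:4].sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.uNuD, self.mNuD, self.mNmD, self.uNmD, self.aN, self.aD]
        )

    @property
    def uN(self) -> float:
        """K4-unmodified proportion at the NR."""
        return 1.0 - self.aN

    @property
    def uD(self) -> float:
        """K4-unmodified proportion at the DNR."""
        return 1.0 - self.aD

    @classmethod
    def from_array(cls, vec: np.ndarray) -> "ChromatinState":
        return cls(*np.asarray(vec, float))


def initial_state_from_levels(
    k27_nr: float, k27_dnr: float, k4_nr: float, k4_dnr: float,
    maxima: dict[str, float],
) -> ChromatinState:
    """Decompose first-date observed levels into a model state.

    Marginal K27 modification probabilities are the observed levels divided
    by their two-year maxima; the four joint K27 states are then formed by
    the independence product (the model's own closure assumption), e.g.
    ``mNmD(0) = P(M_N) * P(M_D)``.
    """
    p_mn = min(k27_nr / maxima["K27_NR"], 1.0)
    p_md = min(k27_dnr / maxima["K27_DNR"], 1.0)
    return ChromatinState(
        uNuD=(1 - p_mn) * (1 - p_md),
        mNuD=p_mn * (1 - p_md),
        mNmD=p_mn * p_md,
        uNmD=(1 - p_mn) * p_md,
        aN=min(k4_nr / maxima["K4_NR"], 1.0),
        aD=min(k4_dnr / maxima["K4_DNR"], 1.0),
    )


# ---------------------------------------------------------------------------
# deterministic dynamics
# ---------------------------------------------------------------------------

def apply_variant(params: ChromatinParams, state_vec: np.ndarray) -> tuple:
    """Effective feedback terms for the configured model variant.

    Returns ``(removal, k4n_repression, k4d_repression)`` — the rate
    factors standing in for ``kappa*aN``, ``phi*(mNuD+mNmD)`` and
    ``psi*(mNmD+uNmD)`` respectively.
    """
    uNuD, mNuD, mNmD, uNmD, aN, aD = state_vec
    removal = params.kappa if params.variant == 2 else params.kappa * aN
    rep_n = params.phi if params.variant == 3 else \
        params.phi * (mNuD + mNmD)
    rep_d = params.psi if params.variant == 4 else \
        params.psi * (mNmD + uNmD)
    return removal, rep_n, rep_d


def ode_rhs(
    state: ChromatinState | np.ndarray, T: float, params: ChromatinParams
) -> np.ndarray:
    """Time derivative (per day) of the six proportions at temperature T."""
    vec = state.as_array() if isinstance(state, ChromatinState) else \
        np.asarray(state, float)
    if np.any(vec < -1e-6) or np.any(vec > 1 + 1e-6) or \
            abs(vec[:4].sum() - 1.0) > 1e-6:
        raise ValueError(f"state outside simplex beyond tolerance: {vec}")
    return _rhs_unchecked(vec, T, params)


def _rhs_unchecked(vec: np.ndarray, T: float, params: ChromatinParams
                   ) -> np.ndarray:
    uNuD, mNuD, mNmD, uNmD, aN, aD = vec
    mu = logistic_rate(T, params.mu)
    nu = logistic_rate(T, params.nu)
    xi = logistic_rate(T, params.xi)
    tau = logistic_rate(T, params.tau_fn)
    removal, rep_n, rep_d = apply_variant(params, vec)
    return np.array([
        params.lam * uNmD - mu * uNuD,
        mu * uNuD - nu * mNuD,
        nu * mNuD - removal * mNmD,
        removal * mNmD - params.lam * uNmD,
        xi * (1.0 - aD) * (1.0 - aN) - rep_n * aN,
        tau * (1.0 - aN) * (1.0 - aD) - rep_d * aD,
    ])


def _jacobian(vec: np.ndarray, T: float, params: ChromatinParams
              ) -> np.ndarray:
    """Analytic Jacobian of the rhs (speeds up the stiff solver)."""
    uNuD, mNuD, mNmD, uNmD, aN, aD = vec
    mu = float(logistic_rate(T, params.mu))
    nu = float(logistic_rate(T, params.nu))
    xi = float(logistic_rate(T, params.xi))
    tau = float(logistic_rate(T, params.tau_fn))
    k, lam = params.kappa, params.lam
    v = params.variant
    removal, rep_n, rep_d = apply_variant(params, vec)
    drem_daN = 0.0 if v == 2 else k
    drep_n = 0.0 if v == 3 else params.phi
    drep_d = 0.0 if v == 4 else params.psi
    J = np.zeros((6, 6))
    J[0, 0] = -mu
    J[0, 3] = lam
    J[1, 0] = mu
    J[1, 1] = -nu
    J[2, 1] = nu
    J[2, 2] = -removal
    J[2, 4] = -drem_daN * mNmD
    J[3, 2] = removal
    J[3, 3] = -lam
    J[3, 4] = drem_daN * mNmD
    # d(aN)/dt = xi*(1-aD)*(1-aN) - rep_n*aN
    J[4, 1] = -drep_n * aN
    J[4, 2] = -drep_n * aN
    J[4, 4] = -xi * (1.0 - aD) - rep_n
    J[4, 5] = -xi * (1.0 - aN)
    # d(aD)/dt = tau*(1-aN)*(1-aD) - rep_d*aD
    J[5, 2] = -drep_d * aD
    J[5, 3] = -drep_d * aD
    J[5, 4] = -tau * (1.0 - aD)
    J[5, 5] = -tau * (1.0 - aN) - rep_d
    return J


@numba.njit(cache=True)
def _rhs_compiled(y, Tc, p):
    """Compiled copy of the rhs; p = 17-vector of flat parameters.

    Kept in exact correspondence with :func:`_rhs_unchecked`; a test
    asserts agreement on random states.
    """
    uNuD, mNuD, mNmD, uNmD, aN, aD = y[0], y[1], y[2], y[3], y[4], y[5]
    zeta, alpha, th1 = p[0], p[1], p[2]
    eta, beta, th2 = p[3], p[4], p[5]
    iota, gamma, th3 = p[6], p[7], p[8]
    rho_amp, eps, th4 = p[9], p[10], p[11]
    kappa, lam, phi, psi = p[12], p[13], p[14], p[15]
    variant = int(p[16])
    mu = zeta / (1.0 + np.exp(min(max(alpha * (Tc - th1), -500.0), 500.0)))
    nu = eta / (1.0 + np.exp(min(max(-beta * (Tc - th2), -500.0), 500.0)))
    xi = iota / (1.0 + np.exp(min(max(-gamma * (Tc - th3), -500.0), 500.0)))
    ta = rho_amp / (1.0 + np.exp(min(max(eps * (Tc - th4), -500.0), 500.0)))
    removal = kappa if variant == 2 else kappa * aN
    rep_n = phi if variant == 3 else phi * (mNuD + mNmD)
    rep_d = psi if variant == 4 else psi * (mNmD + uNmD)
    out = np.empty(6)
    out[0] = lam * uNmD - mu * uNuD
    out[1] = mu * uNuD - nu * mNuD
    out[2] = nu * mNuD - removal * mNmD
    out[3] = removal * mNmD - lam * uNmD
    out[4] = xi * (1.0 - aD) * (1.0 - aN) - rep_n * aN
    out[5] = ta * (1.0 - aN) * (1.0 - aD) - rep_d * aD
    return out


@numba.njit(cache=True)
def _integrate_rk45(t_grid, y0, p, tt, tv, rtol, atol):
    """Adaptive Dormand–Prince RK45 with dense output at ``t_grid``.

    Explicit with step-size control; the fastest transition rate bounds
    the stable step, which stays cheap in compiled code even for rates at
    the parameter upper bound. Temperature forcing is piecewise-linear
    through (tt, tv).
    """
    # Dormand-Prince coefficients
    c2, c3, c4, c5 = 1.0 / 5, 3.0 / 10, 4.0 / 5, 8.0 / 9
    out = np.empty((len(t_grid), 6))
    t = t_grid[0]
    y = y0.copy()
    gi = 0
    h = 0.1
    max_rate = max(p[0], p[3], p[6], p[9], p[12], p[13], p[14], p[15])
    h_max = min(1.0, 2.0 / max(max_rate, 1e-6))
    h = min(h, h_max)
    t_end = t_grid[-1]
    k1 = _rhs_compiled(y, np.interp(t, tt, tv), p)
    n_reject = 0
    while gi < len(t_grid):
        while gi < len(t_grid) and t_grid[gi] <= t + 1e-12:
            out[gi] = y
            gi += 1
        if gi >= len(t_grid):
            break
        h = min(h, t_grid[gi] - t)
        # stage evaluations
        k2 = _rhs_compiled(y + h * (k1 / 5.0),
                           np.interp(t + c2 * h, tt, tv), p)
        k3 = _rhs_compiled(y + h * (3.0 / 40 * k1 + 9.0 / 40 * k2),
                           np.interp(t + c3 * h, tt, tv), p)
        k4 = _rhs_compiled(
            y + h * (44.0 / 45 * k1 - 56.0 / 15 * k2 + 32.0 / 9 * k3),
            np.interp(t + c4 * h, tt, tv), p)
        k5 = _rhs_compiled(
            y + h * (19372.0 / 6561 * k1 - 25360.0 / 2187 * k2
                     + 64448.0 / 6561 * k3 - 212.0 / 729 * k4),
            np.interp(t + c5 * h, tt, tv), p)
        k6 = _rhs_compiled(
            y + h * (9017.0 / 3168 * k1 - 355.0 / 33 * k2
                     + 46732.0 / 5247 * k3 + 49.0 / 176 * k4
                     - 5103.0 / 18656 * k5),
            np.interp(t + h, tt, tv), p)
        y5 = y + h * (35.0 / 384 * k1 + 500.0 / 1113 * k3
                      + 125.0 / 192 * k4 - 2187.0 / 6784 * k5
                      + 11.0 / 84 * k6)
        k7 = _rhs_compiled(y5, np.interp(t + h, tt, tv), p)
        y4 = y + h * (5179.0 / 57600 * k1 + 7571.0 / 16695 * k3
                      + 393.0 / 640 * k4 - 92097.0 / 339200 * k5
                      + 187.0 / 2100 * k6 + 1.0 / 40 * k7)
        # error control
        err = 0.0
        for j in range(6):
            sc = atol + rtol * max(abs(y[j]), abs(y5[j]))
            e = (y5[j] - y4[j]) / sc
            err += e * e
        err = np.sqrt(err / 6.0)
        if err <= 1.0:
            t += h
            y = y5
            k1 = k7  # FSAL
            n_reject = 0
        else:
            n_reject += 1
            if n_reject > 50:
                return out[:gi], t, -1.0
        fac = 0.9 * err ** -0.2 if err > 0 else 5.0
        h = h * min(5.0, max(0.2, fac))
        h = min(h, h_max)
        if h < 1e-12:
            return out[:gi], t, -1.0
        if t + h > t_end:
            h = t_end - t if t_end > t else h
    return out, t, 1.0


def simulate(
    params: ChromatinParams,
    temp: TemperatureSeries,
    t_grid: np.ndarray,
    init: ChromatinState,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the model over ``t_grid`` (days from the record start).

    Temperature is interpolated piecewise-linearly to a continuous
    forcing; the integrator is an adaptive embedded Runge–Kutta (4)5
    pair with the requested tolerances. Returns an array of shape
    ``(len(t_grid), 6)`` in the order ``uNuD, mNuD, mNmD, uNmD, aN, aD``;
    tiny numerical excursions outside [0, 1] (below 1e-6) are projected
    back onto the feasible set.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    span_days = (temp.end - temp.start).total_seconds() / 86400.0
    if t_grid[0] < -1e-9 or t_grid[-1] > span_days + 1e-9:
        raise ValueError(
            f"t_grid [{t_grid[0]}, {t_grid[-1]}] exceeds temperature "
            f"coverage [0, {span_days:.1f}] days"
        )
    d = params.to_dict()
    p = np.array([
        d["zeta"], d["alpha"], d["theta1"],
        d["eta"], d["beta"], d["theta2"],
        d["iota"], d["gamma"], d["theta3"],
        d["rho_amp"], d["epsilon"], d["theta4"],
        d["kappa"], d["lambda"], d["phi"], d["psi"],
        float(d["variant"]),
    ])
    tt = temp.days_since_start()
    out, t_last, status = _integrate_rk45(
        t_grid, init.as_array(), p, tt, temp.values, rtol, atol
    )
    if status < 0:
        raise RuntimeError(f"ODE solver failed; last good time t={t_last}")
    low, high = out.min(), out.max()
    if low < -1e-6 or high > 1 + 1e-6:
        raise RuntimeError(
            f"trajectory left [0,1] beyond tolerance (min {low}, max {high})"
        )
    return np.clip(out, 0.0, 1.0)


def find_fixed_point(params: ChromatinParams, T: float) -> ChromatinState:
    """Steady state under constant temperature, by direct root finding.

    Independent of the time integrator: solves the cyclic-flux balance for
    the K27 states and the two K4 balance equations self-consistently via
    a 1-d root find in aN. Used as an oracle for long-horizon simulations.
    """
    mu = float(logistic_rate(T, params.mu))
    nu = float(logistic_rate(T, params.nu))
    xi = float(logistic_rate(T, params.xi))
    tau = float(logistic_rate(T, params.tau_fn))

    def k27_given_an(aN):
        removal = params.kappa if params.variant == 2 else params.kappa * aN
        rates = np.array([mu, nu, removal, params.lam])
        if np.any(rates <= 0):
            # a dead transition accumulates all mass in its source state
            w = np.zeros(4)
            w[int(np.argmin(rates))] = 1.0
            return w
        w = 1.0 / rates  # balanced cyclic flux: occupancy ∝ residence time
        return w / w.sum()

    def aD_given(aN, k27):
        rep_d = params.psi if params.variant == 4 else \
            params.psi * (k27[2] + k27[3])
        g = tau * (1.0 - aN)
        if g + rep_d <= 0:
            return 0.0
        return g / (g + rep_d)

    def residual(aN):
        k27 = k27_given_an(aN)
        aD = aD_given(aN, k27)
        rep_n = params.phi if params.variant == 3 else \
            params.phi * (k27[1] + k27[2])
        return xi * (1.0 - aD) * (1.0 - aN) - rep_n * aN

    r0, r1 = residual(0.0), residual(1.0)
    if r0 <= 0:
        aN = 0.0
    elif r1 >= 0:
        aN = 1.0
    else:
        aN = brentq(residual, 0.0, 1.0, xtol=1e-14)
    k27 = k27_given_an(aN)
    return ChromatinState(*k27, aN=aN, aD=aD_given(aN, k27))


# ---------------------------------------------------------------------------
# stochastic per-locus counterpart
# ---------------------------------------------------------------------------

def simulate_stochastic(
    params: ChromatinParams,
    temp: TemperatureSeries,
    t_grid: np.ndarray,
    init: ChromatinState,
    n_cells: int,
    seed: int,
    dt: float = 0.02,
    coupling: Literal["ensemble", "per-cell"] = "ensemble",
) -> np.ndarray:
    """Finite-population jump-process counterpart of :func:`simulate`.

    Each of ``n_cells`` cells carries one locus with a discrete joint
    state (4 K27 states x binary K4 at NR and DNR — 16 joint states, the
    in-cis assumption). Transitions fire as time-inhomogeneous Poisson
    events, advanced by binomial tau-leaping with step ``dt`` (days).

    ``coupling="ensemble"`` (default) evaluates the feedback terms on the
    current ensemble proportions (mean-field closure); under the
    independence assumption its ensemble mean reproduces the deterministic
    equations exactly. ``coupling="per-cell"`` gates each locus on its own
    mark states instead (feedback in cis).

    Returns proportions at ``t_grid`` with the same column order as
    :func:`simulate`.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    t_grid = np.asarray(t_grid, dtype=float)
    T = temp.interpolator()

    idx = np.arange(16)
    k27_of = idx // 4
    k4n_of = (idx % 4) // 2
    k4d_of = idx % 2

    # multinomial initial assignment from the independence-factorised state
    p_k27 = np.array([init.uNuD, init.mNuD, init.mNmD, init.uNmD])
    p_joint = (
        p_k27[k27_of]
        * np.where(k4n_of == 1, init.aN, 1 - init.aN)
        * np.where(k4d_of == 1, init.aD, 1 - init.aD)
    )
    counts = rng.multinomial(n_cells, p_joint / p_joint.sum())

    out = np.empty((len(t_grid), 6))
    t = float(t_grid[0])
    gi = 0

    def record():
        nonlocal gi
        frac = counts / n_cells
        out[gi] = [
            frac[k27_of == 0].sum(), frac[k27_of == 1].sum(),
            frac[k27_of == 2].sum(), frac[k27_of == 3].sum(),
            frac[k4n_of == 1].sum(), frac[k4d_of == 1].sum(),
        ]
        gi += 1

    target_k27 = ((k27_of + 1) % 4) * 4 + (idx % 4)
    target_k4n_up = idx + 2
    target_k4n_down = idx - 2
    target_k4d_up = idx + 1
    target_k4d_down = idx - 1

    while gi < len(t_grid):
        while gi < len(t_grid) and t_grid[gi] <= t + 1e-9:
            record()
        if gi >= len(t_grid):
            break
        step = min(dt, t_grid[gi] - t)
        Tc = float(T(t + 0.5 * step))
        mu = float(logistic_rate(Tc, params.mu))
        nu = float(logistic_rate(Tc, params.nu))
        xi = float(logistic_rate(Tc, params.xi))
        tau = float(logistic_rate(Tc, params.tau_fn))

        frac = counts / n_cells
        aN_e = frac[k4n_of == 1].sum()
        aD_e = frac[k4d_of == 1].sum()
        mN_e = frac[np.isin(k27_of, (1, 2))].sum()   # mNuD + mNmD
        mD_e = frac[np.isin(k27_of, (2, 3))].sum()   # mNmD + uNmD

        if coupling == "ensemble":
            removal_fac = params.kappa if params.variant == 2 else \
                params.kappa * aN_e
            removal = np.full(16, removal_fac)
            gain_n = xi * (1.0 - aD_e)
            gain_d = tau * (1.0 - aN_e)
            loss_n = params.phi if params.variant == 3 else params.phi * mN_e
            loss_d = params.psi if params.variant == 4 else params.psi * mD_e
            k4n_up = np.where(k4n_of == 0, gain_n, 0.0)
            k4n_down = np.where(k4n_of == 1, loss_n, 0.0)
            k4d_up = np.where(k4d_of == 0, gain_d, 0.0)
            k4d_down = np.where(k4d_of == 1, loss_d, 0.0)
        else:
            removal = params.kappa * (
                np.ones(16) if params.variant == 2 else k4n_of.astype(float)
            )
            mN_cell = np.isin(k27_of, (1, 2)).astype(float)
            mD_cell = np.isin(k27_of, (2, 3)).astype(float)
            k4n_up = np.where(k4n_of == 0, xi * (1.0 - k4d_of), 0.0)
            k4n_down = np.where(
                k4n_of == 1,
                params.phi * (1.0 if params.variant == 3 else mN_cell), 0.0)
            k4d_up = np.where(k4d_of == 0, tau * (1.0 - k4n_of), 0.0)
            k4d_down = np.where(
                k4d_of == 1,
                params.psi * (1.0 if params.variant == 4 else mD_cell), 0.0)

        k27_rate = np.select(
            [k27_of == 0, k27_of == 1, k27_of == 2, k27_of == 3],
            [np.full(16, mu), np.full(16, nu), removal,
             np.full(16, params.lam)],
        )

        # competing channels: per source state, multinomial split of the
        # total jump probability 1-exp(-R*dt) proportional to channel rates
        channel_rates = np.stack([k27_rate, k4n_up, k4n_down,
                                  k4d_up, k4d_down])
        channel_targets = np.stack([target_k27, target_k4n_up,
                                    target_k4n_down, target_k4d_up,
                                    target_k4d_down])
        total = channel_rates.sum(axis=0)
        p_jump = np.where(total > 0, -np.expm1(-total * step), 0.0)
        new_counts = counts.copy()
        for i in range(16):
            if counts[i] == 0 or total[i] <= 0:
                continue
            probs = channel_rates[:, i] / total[i] * p_jump[i]
            stay = 1.0 - probs.sum()
            draw = rng.multinomial(counts[i], np.append(probs, max(stay, 0)))
            for ch in range(5):
                if draw[ch]:
                    new_counts[i] -= draw[ch]
                    new_counts[channel_targets[ch, i]] += draw[ch]
        counts = new_counts
        t += step
    while gi < len(t_grid):
        record()
    return out


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def scale_states_to_levels(
    trajectories: np.ndarray, observed_maxima: dict[str, float]
) -> dict[str, np.ndarray]:
    """Map state proportions to observable ChIP levels.

    The summed K27 occupancy at each region (mNuD+mNmD at the NR,
    mNmD+uNmD at the DNR) and the K4 occupancies (aN, aD) are multiplied
    by the observed two-year maximum level of the matching series.
    """
    for key, v in observed_maxima.items():
        if v <= 0:
            raise ValueError(f"maximum for {key} must be > 0")
    traj = np.atleast_2d(np.asarray(trajectories, float))
    return {
        "K27_NR": (traj[:, 1] + traj[:, 2]) * observed_maxima["K27_NR"],
        "K27_DNR": (traj[:, 2] + traj[:, 3]) * observed_maxima["K27_DNR"],
        "K4_NR": traj[:, 4] * observed_maxima["K4_NR"],
        "K4_DNR": traj[:, 5] * observed_maxima["K4_DNR"],
    }


def predict_mrna(
    k4_nr_level: np.ndarray, sigma: float, omega: float,
    standardise_to: np.ndarray | None = None,
) -> np.ndarray:
    """mRNA (log10) from the K4 level at the NR: sigma*log10(K4) + omega.

    If ``standardise_to`` is given (an observed log10 mRNA series), the
    prediction is z-scored and rescaled to the observed mean and SD so
    that seasonal amplitudes are comparable across model variants.
    """
    k4 = np.asarray(k4_nr_level, dtype=float)
    if np.any(k4 <= 0):
        raise ValueError("K4 level must be strictly positive for log10")
    pred = sigma * np.log10(k4) + omega
    if standardise_to is not None:
        obs = np.asarray(standardise_to, float)
        sd = pred.std()
        if sd > 0:
            pred = (pred - pred.mean()) / sd * obs.std() + obs.mean()
    return pred
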