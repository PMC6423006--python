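"""Recurrent-event history generators.

Two event-generating processes are provided:

* a modulated Poisson process with Weibull baseline rate
  ``rho0(t) = lam * kappa * (lam t)^(kappa-1)`` and multiplicative
  covariate effect ``exp(eta*x + zeta*z)``, simulated exactly by
  inverting the cumulative intensity (no thinning);

* a progressive Markov process on states 0, 1, ..., Km (the cumulative
  event count) in which each event escalates the baseline transition
  rate by a factor ``exp(alpha)`` up to the (K+1)st event, constant
  thereafter, with the same multiplicative covariate effect.

Calibration helpers pin the expected baseline event count at a horizon,
the Markov one via the matrix exponential of the transition intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

__all__ = [
    "WeibullPoissonModel",
    "MarkovModel",
    "EventHistory",
    "simulate_poisson_history",
    "simulate_poisson_cohort",
    "calibrate_weibull",
    "build_intensity_matrix",
    "markov_expected_count",
    "calibrate_markov_q0",
    "simulate_markov_history",
    "simulate_markov_cohort",
]


@dataclass(frozen=True)
class WeibullPoissonModel:
    """Poisson process with rate rho0(t) * exp(eta*x + zeta*z).

    rho0(t) = lam*kappa*(lam t)^(kappa-1), cumulative mu0(t) = (lam t)^kappa.
    """

    lam: float
    kappa: float
    eta: float = 0.0
    zeta: float = 0.0

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("lam and kappa must be positive")

    def mu0(self, t):
        """Cumulative baseline rate (lam*t)^kappa."""
        return (self.lam * np.asarray(t, dtype=float)) ** self.kappa

    def mu0_inv(self, u):
        """Inverse of mu0: t = u^(1/kappa) / lam."""
        return np.asarray(u, dtype=float) ** (1.0 / self.kappa) / self.lam

    def rho0(self, t):
        t = np.asarray(t, dtype=float)
        return self.lam * self.kappa * (self.lam * t) ** (self.kappa - 1.0)


@dataclass(frozen=True)
class MarkovModel:
    """Progressive Markov process with escalating transition rates.

    In state k (current event count) the baseline transition rate is
    ``q_k = q0 * exp(alpha * min(k, K+1))`` for k = 0, ..., Km-1: each of
    the first K+1 events raises the rate by a factor exp(alpha), after
    which it stays constant.  State Km is absorbing.  Covariates act
    multiplicatively through exp(eta*x + zeta*z).
    """

    q0: float
    alpha: float
    K: int
    Km: int
    eta: float = 0.0
    zeta: float = 0.0

    def __post_init__(self) -> None:
        if self.q0 <= 0:
            raise ValueError("q0 must be positive")
        if self.Km < 1 or self.K < 0:
            raise ValueError("need Km >= 1 and K >= 0")

    def rates(self) -> np.ndarray:
        """Baseline rates q_0, ..., q_{Km-1} out of states 0..Km-1."""
        k = np.arange(self.Km)
        return self.q0 * np.exp(self.alpha * np.minimum(k, self.K + 1))


@dataclass(frozen=True)
class EventHistory:
    """One subject's covariates, censoring time and ordered event times."""

    subject_id: int
    x: float
    z: float
    c: float
    event_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", t)
        if self.c <= 0:
            raise ValueError("censoring time must be positive")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("event times must be strictly increasing")
            if t[0] <= 0 or t[-1] > self.c:
                raise ValueError("event times must lie in (0, c]")


# ---------------------------------------------------------------------------
# Poisson process
# ---------------------------------------------------------------------------

def simulate_poisson_history(
    model: WeibullPoissonModel,
    x: float,
    z: float,
    c: float,
    seed,
    subject_id: int = 0,
) -> EventHistory:
    """Simulate one subject's Poisson event history on (0, c].

    From current time t the next event occurs at
    ``mu0_inv(mu0(t) + E / exp(eta*x + zeta*z))`` with E ~ Exp(1); the
    transformed gaps are exactly exponential so the construction is exact.
    """
    if c <= 0:
        raise ValueError("censoring time must be positive")
    rng = np.random.default_rng(seed)
    g = np.exp(model.eta * x + model.zeta * z)
    u_end = model.mu0(c) * g
    times = []
    u = 0.0
    while True:
        u += rng.exponential()
        if u > u_end:
            break
        times.append(float(model.mu0_inv(u / g)))
    return EventHistory(subject_id, x, z, c, np.array(times))


def simulate_poisson_cohort(
    model: WeibullPoissonModel,
    x: np.ndarray,
    z: np.ndarray,
    c: np.ndarray,
    seed,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized cohort simulation of the Poisson process.

    Returns ``(subject_index, event_time)`` arrays sorted by subject then
    time; subjects with no events simply do not appear.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    c = np.asarray(c, dtype=float)
    n = x.size
    g = np.exp(model.eta * x + model.zeta * z)
    u_end = model.mu0(c) * g

    u = np.zeros(n)
    active = np.arange(n)
    subj_chunks: list[np.ndarray] = []
    time_chunks: list[np.ndarray] = []
    while active.size:
        u[active] += rng.exponential(size=active.size)
        alive = u[active] <= u_end[active]
        active = active[alive]
        if active.size:
            subj_chunks.append(active.copy())
            time_chunks.append(model.mu0_inv(u[active] / g[active]))
    if not subj_chunks:
        return np.empty(0, dtype=np.int64), np.empty(0)
    subj = np.concatenate(subj_chunks)
    times = np.concatenate(time_chunks)
    order = np.lexsort((times, subj))
    return subj[order], times[order]


def calibrate_weibull(kappa: float, target_mean: float, horizon: float) -> float:
    """Weibull scale lam with (lam*horizon)^kappa = target_mean."""
    if target_mean <= 0 or horizon <= 0:
        raise ValueError("target_mean and horizon must be positive")
    return target_mean ** (1.0 / kappa) / horizon


# ---------------------------------------------------------------------------
# Markov process
# ---------------------------------------------------------------------------

def build_intensity_matrix(model: MarkovModel) -> np.ndarray:
    """(Km+1) x (Km+1) transition intensity matrix for the baseline pattern.

    Upper-bidiagonal: Q[j, j] = -q_j, Q[j, j+1] = q_j for j = 0..Km-1 and
    the last row zero (absorbing state).
    """
    q = model.rates()
    Q = np.zeros((model.Km + 1, model.Km + 1))
    idx = np.arange(model.Km)
    Q[idx, idx] = -q
    Q[idx, idx + 1] = q
    return Q


def markov_expected_count(model: MarkovModel, t: float) -> float:
    """Expected event count mu(t | X=0, Z=0) = sum_k k * P_{0k}(t).

    State occupancy probabilities come from the matrix exponential
    exp(Q t) of the transition intensity matrix (Chapman-Kolmogorov).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if t == 0:
        return 0.0
    Q = build_intensity_matrix(model)
    p = expm(Q * t)[0]
    return float(p @ np.arange(model.Km + 1))


def calibrate_markov_q0(
    alpha: float,
    K: int,
    Km: int,
    target_mean: float,
    horizon: float,
) -> float:
    """Root-find q0 so the baseline expected count at the horizon hits target.

    The expected count is strictly increasing in q0, so a bracketing
    solver on [eps, hi] is reliable; hi starts at the homogeneous-Poisson
    guess and is expanded if needed.
    """
    if target_mean <= 0 or horizon <= 0:
        raise ValueError("target_mean and horizon must be positive")

    def f(q0: float) -> float:
        m = MarkovModel(q0=q0, alpha=alpha, K=K, Km=Km)
        return markov_expected_count(m, horizon) - target_mean

    lo = 1e-12
    hi = target_mean / horizon
    tries = 0
    while f(hi) < 0:
        hi *= 2.0
        tries += 1
        if tries > 60:
            raise RuntimeError(
                f"calibrate_markov_q0: could not bracket root (hi={hi:g}, "
                f"f(hi)={f(hi):g}); check alpha/K/Km"
            )
    return brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)


def simulate_markov_history(
    model: MarkovModel,
    x: float,
    z: float,
    c: float,
    seed,
    subject_id: int = 0,
) -> EventHistory:
    """Simulate one subject: sequential Exp(q_k * exp(eta*x + zeta*z)) gaps."""
    if c <= 0:
        raise ValueError("censoring time must be positive")
    rng = np.random.default_rng(seed)
    g = np.exp(model.eta * x + model.zeta * z)
    q = model.rates()
    times = []
    t = 0.0
    k = 0
    while k < model.Km:
        t += rng.exponential(1.0 / (q[k] * g))
        if t > c:
            break
        times.append(t)
        k += 1
    return EventHistory(subject_id, x, z, c, np.array(times))


def simulate_markov_cohort(
    model: MarkovModel,
    x: np.ndarray,
    z: np.ndarray,
    c: np.ndarray,
    seed,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized cohort simulation of the Markov process.

    Returns ``(subject_index, event_time)`` sorted by subject then time.
    All subjects advance one candidate event per sweep, so the number of
    sweeps is bounded by the largest realized event count (at most Km).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    c = np.asarray(c, dtype=float)
    n = x.size
    g = np.exp(model.eta * x + model.zeta * z)
    q = model.rates()

    t = np.zeros(n)
    active = np.arange(n)
    k = 0
    subj_chunks: list[np.ndarray] = []
    time_chunks: list[np.ndarray] = []
    while active.size and k < model.Km:
        rate = q[k] * g[active]
        t[active] += rng.exponential(size=active.size) / rate
        alive = t[active] <= c[active]
        active = active[alive]
        if active.size:
            subj_chunks.append(active.copy())
            time_chunks.append(t[active].copy())
        k += 1
    if not subj_chunks:
        return np.empty(0, dtype=np.int64), np.empty(0)
    subj = np.concatenate(subj_chunks)
    times = np.concatenate(time_chunks)
    order = np.lexsort((times, subj))
    return subj[order], times[order]
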