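"""Semiparametric rate-model fitters on start-stop counting-process data.

Two estimating-equation fitters are provided:

* :func:`fit_marginal` -- the multiplicative marginal rate model in
  which every subject contributes to a single risk set at each event
  time (Andersen-Gill type);

* :func:`fit_partially_conditional` -- the same score restricted within
  time-dependent strata defined by the prior event count, with an
  event-specific Breslow baseline per stratum.

Both solve the profile partial score U(beta) = 0 by damped Newton
iteration and report a model-based (naive) variance from the inverse
observed information and a robust sandwich variance built from
per-subject score residuals (event terms minus the Breslow-compensator
terms, aggregated over all rows of a subject).

Risk-set convention: a row (start, stop] is at risk for events at times
t with start < t <= stop.  Tied event times share the Breslow
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

__all__ = [
    "CountingData",
    "FitResult",
    "to_counting_data",
    "counting_data_from_cohort",
    "fit_marginal",
    "fit_partially_conditional",
    "wald_ci",
]


@dataclass
class CountingData:
    """Start-stop representation of recurrent-event follow-up.

    One row per at-risk interval (start, stop]; ``status`` is 1 when the
    interval ends in an event; ``stratum`` is 1 + the number of the
    subject's events strictly before ``start`` (optionally capped).
    ``covariates`` is an (n_rows, p) array with named columns.
    """

    subject: np.ndarray          # subject identifiers, one per row
    start: np.ndarray
    stop: np.ndarray
    status: np.ndarray           # 0/1
    stratum: np.ndarray          # 1-based
    covariates: np.ndarray       # (n_rows, p)
    covariate_names: list[str] = field(default_factory=lambda: ["x"])

    def __post_init__(self) -> None:
        self.subject = np.asarray(self.subject)
        self.start = np.asarray(self.start, dtype=float)
        self.stop = np.asarray(self.stop, dtype=float)
        self.status = np.asarray(self.status, dtype=np.int8)
        self.stratum = np.asarray(self.stratum, dtype=np.int64)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.start.size:
            self.covariates = self.covariates.T
        if np.any(self.start >= self.stop):
            raise ValueError("intervals must satisfy start < stop")
        if np.any(self.stratum < 1):
            raise ValueError("strata are 1-based positive integers")

    @property
    def n_rows(self) -> int:
        return self.start.size

    @property
    def n_subjects(self) -> int:
        return np.unique(self.subject).size

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def columns(self, names: list[str]) -> np.ndarray:
        """Covariate sub-matrix for the given column names."""
        idx = [self.covariate_names.index(c) for c in names]
        return self.covariates[:, idx]

    # -- I/O -----------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.subject,
                "start": self.start,
                "stop": self.stop,
                "status": self.status,
                "stratum": self.stratum,
            }
        )
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountingData":
        fixed = {"id", "start", "stop", "status", "stratum"}
        missing = fixed - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        cov_names = [c for c in df.columns if c not in fixed]
        return cls(
            subject=df["id"].to_numpy(),
            start=df["start"].to_numpy(dtype=float),
            stop=df["stop"].to_numpy(dtype=float),
            status=df["status"].to_numpy(),
            stratum=df["stratum"].to_numpy(),
            covariates=df[cov_names].to_numpy(dtype=float),
            covariate_names=cov_names,
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "CountingData":
        return cls.from_dataframe(pd.read_csv(path, float_precision="round_trip"))


def to_counting_data(
    histories,
    pool_stratum_at: int | None = None,
    covariate_names: list[str] | None = None,
) -> CountingData:
    """Convert :class:`~recurrates.simulate.EventHistory` objects to rows.

    Each subject yields one row per inter-event interval plus a final
    censored row; stratum = prior event count + 1, capped at
    ``pool_stratum_at`` when given.
    """
    subj, start, stop, status, stratum, xs, zs = [], [], [], [], [], [], []
    for h in histories:
        t = np.asarray(h.event_times, dtype=float)
        if t.size and t[-1] > h.c:
            raise ValueError(f"subject {h.subject_id}: event time beyond c")
        bounds = np.concatenate([[0.0], t, [h.c]])
        # drop a zero-length final row if the last event fell exactly at c
        if t.size and t[-1] == h.c:
            bounds = bounds[:-1]
        k = bounds.size - 1
        for j in range(k):
            subj.append(h.subject_id)
            start.append(bounds[j])
            stop.append(bounds[j + 1])
            status.append(1 if j < t.size else 0)
            s = j + 1
            if pool_stratum_at is not None:
                s = min(s, pool_stratum_at)
            stratum.append(s)
            xs.append(h.x)
            zs.append(h.z)
    cov = np.column_stack([xs, zs])
    names = covariate_names or ["x", "z"]
    return CountingData(
        subject=np.asarray(subj),
        start=np.asarray(start),
        stop=np.asarray(stop),
        status=np.asarray(status),
        stratum=np.asarray(stratum),
        covariates=cov,
        covariate_names=names,
    )


def counting_data_from_cohort(
    x: np.ndarray,
    z: np.ndarray | None,
    c: np.ndarray,
    event_subj: np.ndarray,
    event_times: np.ndarray,
    pool_stratum_at: int | None = None,
) -> CountingData:
    """Vectorized start-stop construction from cohort arrays.

    ``event_subj``/``event_times`` must be sorted by subject then time
    (the layout produced by the cohort simulators).  Covariates are
    ``x`` alone when z is None, else ``(x, z)``.
    """
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    n = x.size
    counts = np.bincount(event_subj, minlength=n)

    # guard: an event exactly at c would make the censored row zero-length
    last_of_subj = np.cumsum(counts) - 1
    has_ev = counts > 0
    at_c = np.zeros(n, dtype=bool)
    at_c[has_ev] = event_times[last_of_subj[has_ev]] == c[has_ev]

    rows_per = counts + 1 - at_c.astype(np.int64)
    total = int(rows_per.sum())
    base = np.concatenate([[0], np.cumsum(rows_per)])

    start = np.zeros(total)
    stop = np.empty(total)
    status = np.zeros(total, dtype=np.int8)

    ev_base = np.concatenate([[0], np.cumsum(counts)])
    rank = np.arange(event_subj.size) - ev_base[event_subj]
    ev_pos = base[event_subj] + rank
    stop[ev_pos] = event_times
    status[ev_pos] = 1
    nxt = ev_pos + 1
    keep = nxt < base[event_subj + 1]
    start[nxt[keep]] = event_times[keep]
    # censored rows: last row of each subject unless the subject's final
    # event landed exactly at c
    cens_pos = base[1:] - 1
    cens_mask = ~at_c
    stop[cens_pos[cens_mask]] = c[cens_mask]

    row_subj = np.repeat(np.arange(n), rows_per)
    stratum = np.arange(total) - base[row_subj] + 1
    if pool_stratum_at is not None:
        np.minimum(stratum, pool_stratum_at, out=stratum)

    if z is None:
        cov = x[row_subj][:, None]
        names = ["x"]
    else:
        z = np.asarray(z, dtype=float)
        cov = np.column_stack([x[row_subj], z[row_subj]])
        names = ["x", "z"]
    return CountingData(
        subject=row_subj,
        start=start,
        stop=stop,
        status=status,
        stratum=stratum,
        covariates=cov,
        covariate_names=names,
    )


# ---------------------------------------------------------------------------
# Score engine
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimated log rate ratios with naive and robust standard errors."""

    beta: np.ndarray
    naive_se: np.ndarray
    robust_se: np.ndarray
    score_norm: float
    baseline: dict[int, tuple[np.ndarray, np.ndarray]]  # stratum -> (times, d(mu))
    n_events: int
    n_subjects: int
    converged: bool
    covariate_names: list[str]
    vcov_naive: np.ndarray | None = None
    vcov_robust: np.ndarray | None = None
    n_iter: int = 0
    model: str = "marginal"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "exp(coef)": np.exp(self.beta),
                "naive_se": self.naive_se,
                "robust_se": self.robust_se,
            },
            index=self.covariate_names,
        )


def _suffix_sums(keys: np.ndarray, values: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """For each query t, sum of values[i] over keys[i] >= t.

    values may be (n,) or (n, p); returns matching (m,) or (m, p).
    """
    order = np.argsort(keys, kind="stable")
    sk = keys[order]
    sv = values[order]
    rc = np.concatenate([np.cumsum(sv[::-1], axis=0)[::-1], np.zeros_like(sv[:1])])
    idx = np.searchsorted(sk, queries, side="left")
    return rc[idx]


class _StratumWork:
    """Pre-sorted per-stratum arrays reused across Newton iterations."""

    def __init__(self, start, stop, status, X, subj_codes):
        self.start = start
        self.stop = stop
        self.X = X
        self.subj = subj_codes
        ev = status == 1
        order = np.argsort(stop[ev], kind="stable")
        self.ev_times = stop[ev][order]
        self.ev_X = X[ev][order]
        self.ev_subj = subj_codes[ev][order]
        self.n_events = self.ev_times.size
        # sort orders for suffix sums, fixed across iterations
        self.order_stop = np.argsort(stop, kind="stable")
        self.order_start = np.argsort(start, kind="stable")
        self.sorted_stop = stop[self.order_stop]
        self.sorted_start = start[self.order_start]
        self.idx_stop = np.searchsorted(self.sorted_stop, self.ev_times, "left")
        self.idx_start = np.searchsorted(self.sorted_start, self.ev_times, "left")

    def _risk_sums(self, vals: np.ndarray) -> np.ndarray:
        """sum over rows at risk (start < t <= stop) of vals, per event time."""
        v_stop = vals[self.order_stop]
        v_start = vals[self.order_start]
        zero = np.zeros_like(vals[:1])
        rc_stop = np.concatenate([np.cumsum(v_stop[::-1], axis=0)[::-1], zero])
        rc_start = np.concatenate([np.cumsum(v_start[::-1], axis=0)[::-1], zero])
        return rc_stop[self.idx_stop] - rc_start[self.idx_start]

    def score_pieces(self, beta: np.ndarray):
        """(loglik, score, information) contributions of this stratum."""
        if self.n_events == 0:
            p = beta.size
            return 0.0, np.zeros(p), np.zeros((p, p))
        w = np.exp(self.X @ beta)
        p = beta.size
        s0 = self._risk_sums(w)
        s1 = self._risk_sums(w[:, None] * self.X)
        xx = self.X[:, :, None] * self.X[:, None, :]
        s2 = self._risk_sums(w[:, None, None] * xx).reshape(-1, p, p)
        xbar = s1 / s0[:, None]
        loglik = float(np.sum(self.ev_X @ beta) - np.sum(np.log(s0)))
        score = (self.ev_X - xbar).sum(axis=0)
        info = (s2 / s0[:, None, None]).sum(axis=0) - np.einsum(
            "ij,ik->jk", xbar, xbar
        )
        return loglik, score, info

    def residual_pieces(self, beta: np.ndarray, resid: np.ndarray) -> None:
        """Accumulate per-subject score residuals into resid (n_subj, p).

        Event part: sum over own events of (x_i - xbar(t)).  Compensator
        part: for every row at risk at an event time t,
        w_row * (x_row - xbar(t)) / S0(t).
        """
        if self.n_events == 0:
            return
        w = np.exp(self.X @ beta)
        s0 = self._risk_sums(w)
        s1 = self._risk_sums(w[:, None] * self.X)
        xbar = s1 / s0[:, None]
        np.add.at(resid, self.ev_subj, self.ev_X - xbar)
        # cumulative event-time sums of 1/S0 and xbar/S0, then per-row window
        a = np.concatenate([[0.0], np.cumsum(1.0 / s0)])
        b = np.vstack([np.zeros(beta.size), np.cumsum(xbar / s0[:, None], axis=0)])
        hi = np.searchsorted(self.ev_times, self.stop, side="right")
        lo = np.searchsorted(self.ev_times, self.start, side="right")
        comp = w[:, None] * (self.X * (a[hi] - a[lo])[:, None] - (b[hi] - b[lo]))
        np.add.at(resid, self.subj, -comp)

    def breslow(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Unique event times and Breslow increments d(mu) = d(t)/S0(t)."""
        if self.n_events == 0:
            return np.empty(0), np.empty(0)
        w = np.exp(self.X @ beta)
        s0 = self._risk_sums(w)
        uniq, first, counts = np.unique(
            self.ev_times, return_index=True, return_counts=True
        )
        return uniq, counts / s0[first]


def _prepare_strata(data: CountingData, X: np.ndarray, pooled: bool):
    codes, _ = pd.factorize(data.subject)
    works = []
    if pooled:
        works.append(_StratumWork(data.start, data.stop, data.status, X, codes))
    else:
        for s in np.unique(data.stratum):
            m = data.stratum == s
            works.append(
                _StratumWork(data.start[m], data.stop[m], data.status[m], X[m], codes[m])
            )
    n_subj = int(codes.max()) + 1 if codes.size else 0
    return works, n_subj


def _newton(works, p, n_subj, max_iter=50):
    """Damped Newton on the profile partial score.

    The absolute convergence tolerance scales with the event count: the
    score is a sum over events, so its float noise floor does too.  The
    line search accepts a step when it reduces the score norm (or raises
    the partial log-likelihood); failure to improve at the noise floor
    terminates with the tolerance check deciding convergence.
    """
    beta = np.zeros(p)
    n_events = sum(w.n_events for w in works)
    tol = max(1e-9, 2e-13 * n_events)

    def evaluate(b):
        ll, score, info = 0.0, np.zeros(p), np.zeros((p, p))
        for w in works:
            l_, s_, i_ = w.score_pieces(b)
            ll += l_
            score += s_
            info += i_
        return ll, score, info

    ll, score, info = evaluate(beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        norm = np.linalg.norm(score)
        if norm <= tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        scale, accepted = 1.0, False
        for _ in range(30):
            cand = beta + scale * step
            ll_c, score_c, info_c = evaluate(cand)
            if np.linalg.norm(score_c) < norm or ll_c > ll:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            break
        beta, ll, score, info = cand, ll_c, score_c, info_c
        if np.linalg.norm(beta) > 50.0:  # separation: score is monotone
            break
    # under separation the score decays to zero along a diverging beta while
    # the information degenerates at the same rate, so the Newton step stays
    # O(1); demand both a small score and a small step for convergence
    converged = False
    if np.linalg.norm(score) <= tol and np.linalg.norm(beta) <= 50.0:
        try:
            step = np.linalg.solve(info, score)
            converged = bool(
                np.linalg.norm(step) <= 1e-3 * (1.0 + np.linalg.norm(beta))
            )
        except np.linalg.LinAlgError:
            converged = False
    return beta, converged, n_iter


def _fit(data: CountingData, covariate_columns, pooled: bool, model: str) -> FitResult:
    if isinstance(covariate_columns, str):
        covariate_columns = [covariate_columns]
    X = data.columns(list(covariate_columns))
    p = X.shape[1]
    if data.n_events == 0:
        raise ValueError("no events in the data; nothing to fit")
    works, n_subj = _prepare_strata(data, X, pooled)

    beta, converged, n_iter = _newton(works, p, n_subj)

    score = np.zeros(p)
    info = np.zeros((p, p))
    for w in works:
        _, s_, i_ = w.score_pieces(beta)
        score += s_
        info += i_
    score_norm = float(np.linalg.norm(score))

    vcov_naive = np.linalg.inv(info)
    resid = np.zeros((n_subj, p))
    for w in works:
        w.residual_pieces(beta, resid)
    B = resid.T @ resid
    vcov_robust = vcov_naive @ B @ vcov_naive

    baseline = {}
    if pooled:
        t, d = works[0].breslow(beta)
        baseline[1] = (t, d)
    else:
        strata = np.unique(data.stratum)
        for s, w in zip(strata, works):
            t, d = w.breslow(beta)
            if t.size:  # strata without events carry no baseline
                baseline[int(s)] = (t, d)

    return FitResult(
        beta=beta,
        naive_se=np.sqrt(np.diag(vcov_naive)),
        robust_se=np.sqrt(np.diag(vcov_robust)),
        score_norm=score_norm,
        baseline=baseline,
        n_events=data.n_events,
        n_subjects=n_subj,
        converged=converged,
        covariate_names=list(covariate_columns),
        vcov_naive=vcov_naive,
        vcov_robust=vcov_robust,
        n_iter=n_iter,
        model=model,
    )


def fit_marginal(data: CountingData, covariate_columns=("x",)) -> FitResult:
    """Fit the marginal rate model (single risk set over all rows)."""
    return _fit(data, covariate_columns, pooled=True, model="marginal")


def fit_partially_conditional(data: CountingData, covariate_columns=("x",)) -> FitResult:
    """Fit the event-count-stratified (partially conditional) rate model.

    Risk sets are restricted within stratum; each stratum gets its own
    Breslow baseline.  Strata without events contribute nothing.
    """
    return _fit(data, covariate_columns, pooled=False, model="pc")


def score_info_residuals(data: CountingData, covariate_columns, beta, pooled: bool):
    """Score, information and per-subject residuals at a fixed beta.

    Used by the asymptotic machinery to evaluate the sandwich components
    E[-dU_i/dbeta] and E[U_i U_i'] by Monte Carlo at a limiting value.
    Returns (score, info, resid) with resid of shape (n_subjects, p).
    """
    if isinstance(covariate_columns, str):
        covariate_columns = [covariate_columns]
    X = data.columns(list(covariate_columns))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    works, n_subj = _prepare_strata(data, X, pooled)
    p = beta.size
    score = np.zeros(p)
    info = np.zeros((p, p))
    for w in works:
        _, s_, i_ = w.score_pieces(beta)
        score += s_
        info += i_
    resid = np.zeros((n_subj, p))
    for w in works:
        w.residual_pieces(beta, resid)
    return score, info, resid


def wald_ci(fit: FitResult, level: float = 0.95) -> dict[str, np.ndarray]:
    """Wald confidence intervals beta +/- z * SE for naive and robust SEs.

    Returns ``{"naive": (p, 2) array, "robust": (p, 2) array}``.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    zq = _norm.ppf(0.5 + level / 2.0)
    out = {}
    for key, se in (("naive", fit.naive_se), ("robust", fit.robust_se)):
        out[key] = np.column_stack([fit.beta - zq * se, fit.beta + zq * se])
    return out
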