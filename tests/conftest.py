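"""Shared fixtures and independent brute-force oracles.

The oracles re-derive the estimating-equation quantities by direct
enumeration (double loops over events and rows) so they stay independent
of the vectorized implementation they check.
"""

import numpy as np
import pytest

from recurrates import EventHistory, to_counting_data


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_score(data, cols, beta, stratified):
    """Profile partial score by direct enumeration."""
    X = data.columns(list(cols))
    beta = np.atleast_1d(np.asarray(beta, float))
    ev = np.flatnonzero(data.status == 1)
    score = np.zeros(beta.size)
    for e in ev:
        t = data.stop[e]
        if stratified:
            at_risk = (
                (data.stratum == data.stratum[e])
                & (data.start < t)
                & (t <= data.stop)
            )
        else:
            at_risk = (data.start < t) & (t <= data.stop)
        w = np.exp(X[at_risk] @ beta)
        xbar = (w[:, None] * X[at_risk]).sum(axis=0) / w.sum()
        score += X[e] - xbar
    return score


def brute_subject_residuals(data, cols, beta, stratified):
    """Per-subject score residuals (event minus compensator terms)."""
    X = data.columns(list(cols))
    beta = np.atleast_1d(np.asarray(beta, float))
    subjects = list(dict.fromkeys(data.subject.tolist()))
    idx = {s: i for i, s in enumerate(subjects)}
    resid = np.zeros((len(subjects), beta.size))
    ev = np.flatnonzero(data.status == 1)
    for e in ev:
        t = data.stop[e]
        if stratified:
            at_risk = (
                (data.stratum == data.stratum[e])
                & (data.start < t)
                & (t <= data.stop)
            )
        else:
            at_risk = (data.start < t) & (t <= data.stop)
        rows = np.flatnonzero(at_risk)
        w = np.exp(X[rows] @ beta)
        s0 = w.sum()
        xbar = (w[:, None] * X[rows]).sum(axis=0) / s0
        resid[idx[data.subject[e]]] += X[e] - xbar
        for r, wr in zip(rows, w):
            resid[idx[data.subject[r]]] -= wr * (X[r] - xbar) / s0
    return resid


def brute_breslow(data, cols, beta, stratum):
    """Breslow increments dN(t)/S0(t) for one stratum, by enumeration."""
    X = data.columns(list(cols))
    beta = np.atleast_1d(np.asarray(beta, float))
    ev = np.flatnonzero((data.status == 1) & (data.stratum == stratum))
    times = np.unique(data.stop[ev])
    inc = []
    for t in times:
        at_risk = (data.stratum == stratum) & (data.start < t) & (t <= data.stop)
        s0 = np.exp(X[at_risk] @ beta).sum()
        d = np.sum(data.stop[ev] == t)
        inc.append(d / s0)
    return times, np.asarray(inc)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture()
def toy4_histories():
    """The 4-subject toy: closed-form solutions for both fitters."""
    return [
        EventHistory(1, 1.0, 0.0, 1.0, np.array([0.5])),
        EventHistory(2, 1.0, 0.0, 1.0, np.array([])),
        EventHistory(3, 0.0, 0.0, 1.0, np.array([0.25, 0.75])),
        EventHistory(4, 0.0, 0.0, 1.0, np.array([])),
    ]


@pytest.fixture()
def toy4_data(toy4_histories):
    return to_counting_data(toy4_histories)


@pytest.fixture()
def random_histories():
    """A deterministic batch of small random histories (10 subjects)."""
    rng = np.random.default_rng(20240917)
    out = []
    for i in range(10):
        k = int(rng.integers(0, 4))
        t = np.sort(rng.uniform(0.01, 0.99, size=k))
        out.append(
            EventHistory(i + 1, float(i % 2), float(rng.integers(0, 2)), 1.0, t)
        )
    return out
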