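"""Covariate joint distributions and censoring schemes.

These objects are shared by the event-history simulators and by the
asymptotic (large-sample limit) calculations: a binary treatment ``X``
paired with either a binary or a normal prognostic covariate ``Z``, and
an effective right-censoring time ``C = min(R, A)`` combining exponential
dropout with administrative end of follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinaryJoint",
    "NormalConfounder",
    "CensoringScheme",
    "solve_binary_joint",
    "sample_covariates",
]


@dataclass(frozen=True)
class BinaryJoint:
    """Joint law of a binary treatment X and binary covariate Z.

    Parameterized by the margins ``pX = P(X=1)``, ``pZ = P(Z=1)`` and the
    odds ratio ``phi``; the four cell probabilities ``pxz = P(X=x, Z=z)``
    are stored explicitly.  Construct via :func:`solve_binary_joint`.
    """

    pX: float
    pZ: float
    phi: float
    p11: float
    p10: float
    p01: float
    p00: float

    def __post_init__(self) -> None:
        cells = (self.p11, self.p10, self.p01, self.p00)
        if any(c < -1e-12 or c > 1 + 1e-12 for c in cells):
            raise ValueError(f"cell probabilities outside [0,1]: {cells}")
        if abs(sum(cells) - 1.0) > 1e-9:
            raise ValueError("cell probabilities do not sum to 1")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        """(p11, p10, p01, p00) as a tuple."""
        return (self.p11, self.p10, self.p01, self.p00)

    def conditional_pz_given_x(self, x: int) -> float:
        """P(Z=1 | X=x)."""
        if x == 1:
            return self.p11 / self.pX
        return self.p01 / (1.0 - self.pX)


@dataclass(frozen=True)
class NormalConfounder:
    """Normal covariate Z | X=x ~ N(theta0 + theta1*x, sigma^2).

    ``theta1 = 0`` encodes independence of X and Z.
    """

    theta0: float
    theta1: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def mean_given_x(self, x: float) -> float:
        return self.theta0 + self.theta1 * x


def solve_binary_joint(pX: float, pZ: float, phi: float) -> BinaryJoint:
    """Unique 2x2 joint law with margins (pX, pZ) and odds ratio phi.

    Solves the Plackett quadratic for ``p11 = P(X=1, Z=1)``:

        phi * (pX - p11) * (pZ - p11) = p11 * (1 - pX - pZ + p11)

    taking the root inside the Frechet bounds
    ``[max(0, pX + pZ - 1), min(pX, pZ)]``.
    """
    if not (0.0 < pX < 1.0 and 0.0 < pZ < 1.0):
        raise ValueError("margins must lie strictly inside (0, 1)")
    if phi <= 0:
        raise ValueError("odds ratio must be positive")

    if phi == 1.0:
        p11 = pX * pZ
    else:
        a = phi - 1.0
        b = -((phi - 1.0) * (pX + pZ) + 1.0)
        c = phi * pX * pZ
        disc = b * b - 4.0 * a * c
        if disc < 0:  # cannot occur for valid inputs; guard anyway
            raise ValueError("no admissible cell probabilities")
        # the (-) root is the admissible one for both phi > 1 and phi < 1
        p11 = (-b - math.sqrt(disc)) / (2.0 * a)

    lo = max(0.0, pX + pZ - 1.0)
    hi = min(pX, pZ)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise ValueError("no admissible cell probabilities")
    p11 = min(max(p11, lo), hi)
    return BinaryJoint(
        pX=pX,
        pZ=pZ,
        phi=phi,
        p11=p11,
        p10=pX - p11,
        p01=pZ - p11,
        p00=1.0 - pX - pZ + p11,
    )


def sample_covariates(
    law: BinaryJoint | tuple[float, NormalConfounder],
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n i.i.d. pairs (x, z).

    X ~ Bernoulli(pX) and Z from its conditional law given X -- binary for
    a :class:`BinaryJoint`, normal for a ``(pX, NormalConfounder)`` pair.
    Returns arrays ``(x, z)`` of length n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(law, BinaryJoint):
        x = (rng.random(n) < law.pX).astype(np.int8)
        pz_x = np.where(
            x == 1,
            law.conditional_pz_given_x(1),
            law.conditional_pz_given_x(0),
        )
        z = (rng.random(n) < pz_x).astype(np.float64)
        return x.astype(np.float64), z
    pX, conf = law
    if not (0.0 < pX < 1.0):
        raise ValueError("pX must lie strictly inside (0, 1)")
    x = (rng.random(n) < pX).astype(np.float64)
    z = rng.normal(conf.theta0 + conf.theta1 * x, conf.sigma)
    return x, z


@dataclass(frozen=True)
class CensoringScheme:
    """Effective censoring C = min(R, A).

    ``A`` is the administrative censoring time and ``R`` an exponential
    dropout time with rate ``r`` chosen so that P(R < A) = dropout_prob;
    ``dropout_prob = 0`` means no random dropout (R = +inf, all C = A).
    """

    A: float
    dropout_prob: float = 0.0
    r: float = field(init=False)

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("administrative censoring time A must be > 0")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValueError("dropout_prob must lie in [0, 1)")
        rate = 0.0
        if self.dropout_prob > 0.0:
            rate = -math.log1p(-self.dropout_prob) / self.A
        object.__setattr__(self, "r", rate)

    def survivor(self, t: float | np.ndarray) -> float | np.ndarray:
        """G(t) = P(C >= t): exp(-r t) on [0, A], zero beyond A."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("t must be non-negative")
        out = np.where(t_arr <= self.A, np.exp(-self.r * t_arr), 0.0)
        if np.isscalar(t) or t_arr.ndim == 0:
            return float(out)
        return out

    def sample(
        self, n: int, seed: int | np.random.SeedSequence | np.random.Generator
    ) -> np.ndarray:
        """Draw n censoring times C_i = min(R_i, A)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        if self.r == 0.0:
            return np.full(n, self.A, dtype=float)
        return np.minimum(rng.exponential(1.0 / self.r, size=n), self.A)


def censoring_survivor(scheme: CensoringScheme, t):
    """Functional alias for :meth:`CensoringScheme.survivor`."""
    return scheme.survivor(t)


def sample_censoring(scheme: CensoringScheme, n: int, seed) -> np.ndarray:
    """Functional alias for :meth:`CensoringScheme.sample`."""
    return scheme.sample(n, seed)
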