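"""Discrete score distributions and their Gaussian-kernel continuization.

Kernel equating replaces the discrete score variable ``X`` (score points
``x_1 < ... < x_J`` with probabilities ``r_j``) by the continuous variable

    X(h) = a (X + h Z) + (1 - a) mu,      a^2 = sigma^2 / (sigma^2 + h^2),

where ``Z`` is standard normal, ``h > 0`` the bandwidth and ``mu``,
``sigma^2`` the mean and variance of the discrete distribution.  The
shrinkage factor ``a`` makes the continuized variable preserve the first
two moments of ``X`` exactly, for every bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DiscreteScoreDistribution",
    "BivariateScoreTable",
    "ContinuizedDistribution",
    "shrinkage_factor",
    "kernel_cdf",
    "kernel_pdf",
    "kernel_pdf_derivative",
    "inverse_cdf",
]

_PROB_SUM_TOL = 1e-8


def _validate_probs(probs: np.ndarray, tol: float = _PROB_SUM_TOL) -> np.ndarray:
    """Clip tiny negatives and renormalize; reject larger violations."""
    probs = np.asarray(probs, dtype=float)
    if np.any(probs < -tol):
        raise ValueError(f"negative probabilities (min {probs.min():.3e})")
    probs = np.clip(probs, 0.0, None)
    total = probs.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"probabilities sum to {total:.8f}, not 1")
    return probs / total


@dataclass(frozen=True)
class DiscreteScoreDistribution:
    """A score distribution on an ordered integer grid.

    Parameters
    ----------
    scores
        Strictly increasing integer score values.
    probs
        Probability per score point; nonnegative, summing to one.
    counts
        Optional observed frequencies on the same grid.  When given they
        carry the raw (pre-smoothing) data needed by resampling-based
        procedures; ``probs`` may differ from ``counts / n`` after
        presmoothing.
    n
        Number of test takers.  Defaults to ``counts.sum()`` when counts
        are available.
    """

    scores: np.ndarray
    probs: np.ndarray
    counts: np.ndarray | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        probs = _validate_probs(np.asarray(self.probs, dtype=float))
        if scores.ndim != 1 or scores.shape != probs.shape:
            raise ValueError("scores and probs must be 1-d arrays of equal length")
        if np.any(np.diff(scores) <= 0):
            raise ValueError("scores must be strictly increasing")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "probs", probs)
        if self.counts is not None:
            counts = np.asarray(self.counts, dtype=float)
            if counts.shape != scores.shape or np.any(counts < 0):
                raise ValueError("counts must be nonnegative and match the score grid")
            object.__setattr__(self, "counts", counts)
            if self.n is None:
                object.__setattr__(self, "n", int(round(counts.sum())))

    @property
    def mean(self) -> float:
        return float(self.scores @ self.probs)

    @property
    def var(self) -> float:
        mu = self.mean
        return float(((self.scores - mu) ** 2) @ self.probs)

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.var))

    def moment(self, p: int) -> float:
        """Raw moment ``E[X^p]``."""
        return float((self.scores**p) @ self.probs)

    @classmethod
    def from_counts(cls, scores, counts) -> "DiscreteScoreDistribution":
        counts = np.asarray(counts, dtype=float)
        n = counts.sum()
        if n <= 0:
            raise ValueError("total count must be positive")
        return cls(scores=np.asarray(scores, dtype=float), probs=counts / n,
                   counts=counts, n=int(round(n)))

    def with_probs(self, probs) -> "DiscreteScoreDistribution":
        """Same grid and raw counts, new (e.g. presmoothed) probabilities."""
        return DiscreteScoreDistribution(scores=self.scores, probs=probs,
                                         counts=self.counts, n=self.n)


@dataclass(frozen=True)
class BivariateScoreTable:
    """Joint (test score, anchor score) probabilities for one population."""

    x_scores: np.ndarray
    a_scores: np.ndarray
    probs: np.ndarray
    counts: np.ndarray | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x_scores, dtype=float)
        a = np.asarray(self.a_scores, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (x.size, a.size):
            raise ValueError("probs must have shape (len(x_scores), len(a_scores))")
        flat = _validate_probs(probs.ravel())
        object.__setattr__(self, "x_scores", x)
        object.__setattr__(self, "a_scores", a)
        object.__setattr__(self, "probs", flat.reshape(probs.shape))
        if self.counts is not None:
            counts = np.asarray(self.counts, dtype=float)
            if counts.shape != probs.shape or np.any(counts < 0):
                raise ValueError("counts must be nonnegative with the same shape")
            object.__setattr__(self, "counts", counts)
            if self.n is None:
                object.__setattr__(self, "n", int(round(counts.sum())))

    @property
    def x_marginal(self) -> DiscreteScoreDistribution:
        counts = None if self.counts is None else self.counts.sum(axis=1)
        return DiscreteScoreDistribution(self.x_scores, self.probs.sum(axis=1),
                                         counts=counts, n=self.n)

    @property
    def a_marginal(self) -> DiscreteScoreDistribution:
        counts = None if self.counts is None else self.counts.sum(axis=0)
        return DiscreteScoreDistribution(self.a_scores, self.probs.sum(axis=0),
                                         counts=counts, n=self.n)

    @classmethod
    def from_counts(cls, x_scores, a_scores, counts) -> "BivariateScoreTable":
        counts = np.asarray(counts, dtype=float)
        n = counts.sum()
        if n <= 0:
            raise ValueError("total count must be positive")
        return cls(x_scores=x_scores, a_scores=a_scores, probs=counts / n,
                   counts=counts, n=int(round(n)))


def shrinkage_factor(sigma2: float, h: float) -> float:
    """Shrinkage factor ``a = sqrt(sigma^2 / (sigma^2 + h^2))``.

    Equals 1 at ``h = 0`` (no smoothing) and decays to 0 as ``h`` grows,
    where the continuized distribution approaches a normal with the same
    mean and variance.
    """
    if sigma2 <= 0:
        raise ValueError("degenerate distribution: variance must be positive")
    if h < 0:
        raise ValueError("bandwidth must be nonnegative")
    return float(np.sqrt(sigma2 / (sigma2 + h * h)))


@dataclass(frozen=True)
class ContinuizedDistribution:
    """A discrete score distribution smoothed with a Gaussian kernel."""

    base: DiscreteScoreDistribution
    h: float
    mu: float = field(init=False)
    sigma2: float = field(init=False)
    a: float = field(init=False)

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("bandwidth must be positive")
        if self.base.scores.size < 2:
            raise ValueError("need at least two score points to continuize")
        object.__setattr__(self, "mu", self.base.mean)
        object.__setattr__(self, "sigma2", self.base.var)
        object.__setattr__(self, "a", shrinkage_factor(self.base.var, self.h))

    # z_j(x) = (x - a x_j - (1-a) mu) / (a h)
    def _z(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x[..., None] - self.a * self.base.scores
                - (1.0 - self.a) * self.mu) / (self.a * self.h)

    def cdf(self, x):
        val = np.clip(stats.norm.cdf(self._z(x)) @ self.base.probs, 0.0, 1.0)
        return float(val) if np.isscalar(x) or np.ndim(x) == 0 else val

    def pdf(self, x):
        val = stats.norm.pdf(self._z(x)) @ self.base.probs / (self.a * self.h)
        return float(val) if np.isscalar(x) or np.ndim(x) == 0 else val

    def pdf_derivative(self, x):
        """Closed-form derivative of the Gaussian-mixture density."""
        z = self._z(x)
        val = (-z * stats.norm.pdf(z)) @ self.base.probs / (self.a * self.h) ** 2
        return float(val) if np.isscalar(x) or np.ndim(x) == 0 else val

    def ppf(self, p):
        return inverse_cdf(self, p)

    @property
    def support(self) -> tuple[float, float]:
        """Bracket guaranteed to contain every quantile of interest."""
        pad = 10.0 * self.h + 10.0 * np.sqrt(self.sigma2)
        return float(self.base.scores[0] - pad), float(self.base.scores[-1] + pad)


def kernel_cdf(cd: ContinuizedDistribution, x):
    """Continuized CDF ``F_h(x; r) = sum_j r_j Phi((x - a x_j - (1-a) mu)/(a h))``."""
    return cd.cdf(x)


def kernel_pdf(cd: ContinuizedDistribution, x):
    """Density of the continuized score variable (Gaussian mixture)."""
    return cd.pdf(x)


def kernel_pdf_derivative(cd: ContinuizedDistribution, x):
    return cd.pdf_derivative(x)


def inverse_cdf(cd: ContinuizedDistribution, p):
    """Quantile function of the continuized distribution.

    The continuized CDF is strictly increasing for ``h > 0``, so a
    bracketing root finder is globally safe.
    """
    scalar = np.isscalar(p) or np.ndim(p) == 0
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p_arr <= 0.0) | (p_arr >= 1.0)):
        raise ValueError("p must lie strictly between 0 and 1")
    lo, hi = cd.support
    out = np.empty_like(p_arr)
    for i, pi in enumerate(p_arr):
        out[i] = optimize.brentq(lambda t: cd.cdf(t) - pi, lo, hi, xtol=1e-12)
    return float(out[0]) if scalar else out
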