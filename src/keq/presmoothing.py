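"""Log-linear presmoothing of score frequencies.

Raw score frequencies are noisy, especially on long tests with modest
samples.  Before equating they are smoothed with a polynomial log-linear
(Poisson) model:

    log E[n_j] = beta_0 + beta_1 x_j + ... + beta_T x_j^T,

fitted by maximum likelihood.  The Poisson score equations force the
fitted distribution to reproduce the observed raw moments of every order
included in the design — the moment-matching property that makes this
family the standard presmoother in observed-score equating.  The
bivariate version smooths a joint (test score, anchor score) table with
marginal polynomials plus selected cross-moment terms.

The fit also supplies a covariance factor ``C`` with ``C @ C.T`` equal to
the asymptotic covariance of the fitted probability vector; it is the
ingredient of the delta-method standard error of equating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import linalg

from .core import BivariateScoreTable, DiscreteScoreDistribution

__all__ = [
    "LoglinearFit",
    "fit_loglinear_univariate",
    "fit_loglinear_bivariate",
    "select_model",
    "cov_factor",
    "multinomial_cov_factor",
    "FittingError",
    "UNIVARIATE_CANDIDATES",
    "BIVARIATE_CANDIDATES",
]

# Default design spaces searched by information-criterion model selection.
UNIVARIATE_CANDIDATES: tuple[int, ...] = (2, 3, 4, 5, 6)
_CROSS_SETS: tuple[tuple[tuple[int, int], ...], ...] = (
    (), ((1, 1),), ((1, 1), (1, 2), (2, 1)), ((1, 1), (2, 2)),
)
BIVARIATE_CANDIDATES: tuple[tuple[int, int, tuple[tuple[int, int], ...]], ...] = tuple(
    (dx, da, cross)
    for dx in (2, 3, 4)
    for da in (2, 3, 4)
    for cross in _CROSS_SETS
)


class FittingError(RuntimeError):
    """Log-linear fit failed to converge or the design is rank deficient."""


def _poly_columns(values: np.ndarray, degree: int) -> list[np.ndarray]:
    """Centered/scaled monomial columns x, x^2, ..., x^degree.

    Standardizing each monomial keeps the IRLS well conditioned; the fit
    is invariant to this affine reparametrization of the design span.
    """
    cols = []
    for d in range(1, degree + 1):
        c = values.astype(float) ** d
        c = (c - c.mean()) / (c.std() if c.std() > 0 else 1.0)
        cols.append(c)
    return cols


@dataclass(frozen=True)
class LoglinearFit:
    """A fitted log-linear presmoothing model.

    ``fitted_probs`` lives on the full score grid (1-d for univariate
    fits, ``(J, L)`` for bivariate fits) and is strictly positive, so
    downstream post-stratification never divides by zero.
    """

    design: dict
    fitted_probs: np.ndarray
    aic: float
    bic: float
    loglik: float
    n_params: int
    n: int
    counts: np.ndarray
    # design matrix without the intercept column, over the flattened grid
    basis: np.ndarray
    x_scores: np.ndarray
    a_scores: np.ndarray | None = None

    @property
    def is_bivariate(self) -> bool:
        return self.a_scores is not None

    def distribution(self) -> DiscreteScoreDistribution:
        if self.is_bivariate:
            raise ValueError("bivariate fit; use table()")
        return DiscreteScoreDistribution(self.x_scores, self.fitted_probs,
                                         counts=self.counts, n=self.n)

    def table(self) -> BivariateScoreTable:
        if not self.is_bivariate:
            raise ValueError("univariate fit; use distribution()")
        return BivariateScoreTable(self.x_scores, self.a_scores, self.fitted_probs,
                                   counts=self.counts, n=self.n)

    def to_dict(self) -> dict:
        return {"design": {k: (list(map(list, v)) if k == "cross" else v)
                           for k, v in self.design.items()},
                "aic": self.aic, "bic": self.bic, "n_params": self.n_params,
                "n": self.n}


def _fit_glm(counts_flat: np.ndarray, basis: np.ndarray, design: dict,
             x_scores: np.ndarray, a_scores: np.ndarray | None) -> LoglinearFit:
    n = counts_flat.sum()
    if n <= 0:
        raise FittingError("total count must be positive")
    X = np.column_stack([np.ones_like(counts_flat, dtype=float), basis])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FittingError(f"rank-deficient design {design}")
    model = sm.GLM(counts_flat, X, family=sm.families.Poisson())
    try:
        res = model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # pragma: no cover - statsmodels failure path
        raise FittingError(f"log-linear fit failed for design {design}: {exc}") from exc
    if not res.converged:
        raise FittingError(f"log-linear fit did not converge for design {design}")
    mu = np.asarray(res.mu, dtype=float)
    probs = mu / mu.sum()
    k = X.shape[1]
    ll = float(res.llf)
    shape = counts_flat.shape if a_scores is None else (x_scores.size, a_scores.size)
    return LoglinearFit(
        design=design,
        fitted_probs=probs.reshape(shape),
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * np.log(n),
        loglik=ll,
        n_params=k,
        n=int(round(n)),
        counts=counts_flat.reshape(shape),
        basis=basis,
        x_scores=np.asarray(x_scores, dtype=float),
        a_scores=None if a_scores is None else np.asarray(a_scores, dtype=float),
    )


def fit_loglinear_univariate(scores, counts, degree: int) -> LoglinearFit:
    """Fit ``log E[n_j] = poly(x_j)`` of the given degree.

    The fitted probabilities match the observed raw moments of orders
    ``1..degree``.
    """
    scores = np.asarray(scores, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if degree >= np.count_nonzero(counts):
        raise FittingError("degree must be below the number of occupied score points")
    basis = np.column_stack(_poly_columns(scores, degree))
    return _fit_glm(counts, basis, {"degree": degree}, scores, None)


def fit_loglinear_bivariate(table: BivariateScoreTable, deg_x: int, deg_a: int,
                            cross: Sequence[tuple[int, int]] = ()) -> LoglinearFit:
    """Fit a joint log-linear model with marginal polynomials and cross terms.

    ``cross`` lists cross-moment orders ``(i, j)`` adding terms
    ``x^i * a^j``; the fit then matches the observed ``E[X^i A^j]``.
    """
    if table.counts is None:
        raise ValueError("bivariate presmoothing needs raw counts")
    x, a = table.x_scores, table.a_scores
    xg, ag = np.meshgrid(x, a, indexing="ij")
    xf, af = xg.ravel(), ag.ravel()
    cols = _poly_columns(xf, deg_x) + _poly_columns(af, deg_a)
    for i, j in cross:
        c = xf**i * af**j
        c = (c - c.mean()) / (c.std() if c.std() > 0 else 1.0)
        cols.append(c)
    design = {"deg_x": deg_x, "deg_a": deg_a, "cross": tuple(tuple(p) for p in cross)}
    return _fit_glm(table.counts.ravel(), np.column_stack(cols), design, x, a)


def select_model(data, candidates=None, criterion: str = "aic") -> LoglinearFit:
    """Fit every candidate design and return the information-criterion winner.

    ``data`` is either ``(scores, counts)`` for univariate candidates
    (integer degrees) or a :class:`BivariateScoreTable` for bivariate
    candidates ``(deg_x, deg_a, cross)``.  Ties break toward fewer
    parameters.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    bivariate = isinstance(data, BivariateScoreTable)
    if candidates is None:
        candidates = BIVARIATE_CANDIDATES if bivariate else UNIVARIATE_CANDIDATES
    fits, failures = [], []
    for cand in candidates:
        try:
            if bivariate:
                fits.append(fit_loglinear_bivariate(data, *cand))
            else:
                fits.append(fit_loglinear_univariate(data[0], data[1], cand))
        except FittingError as exc:
            failures.append(str(exc))
    if not fits:
        raise FittingError("no candidate converged: " + "; ".join(failures))
    return min(fits, key=lambda f: (getattr(f, criterion), f.n_params))


def cov_factor(fit: LoglinearFit) -> np.ndarray:
    """Covariance factor ``C`` of the presmoothed probability vector.

    ``C @ C.T`` is the delta-method asymptotic covariance of the fitted
    probabilities: with ``S = diag(p) - p p^T`` and intercept-free design
    ``B``,

        Cov(p_hat) = (1/n) S B (B^T S B)^{-1} B^T S.

    For a saturated design this reduces to the multinomial covariance
    ``(diag(p) - p p^T) / n``.  Returned flattened over the grid for
    bivariate fits.
    """
    p = fit.fitted_probs.ravel()
    B = fit.basis
    SB = p[:, None] * B - np.outer(p, p @ B)  # S @ B without forming S
    M = B.T @ SB
    try:
        L = linalg.cholesky(M, lower=True)
    except linalg.LinAlgError as exc:
        raise FittingError("singular information matrix") from exc
    # C = (1/sqrt(n)) S B L^{-T}  =>  C C^T = (1/n) S B M^{-1} B^T S
    C = linalg.solve_triangular(L, SB.T, lower=True).T / np.sqrt(fit.n)
    return C


def multinomial_cov_factor(dist: DiscreteScoreDistribution) -> np.ndarray:
    """Covariance factor for an unsmoothed (empirical) distribution.

    ``C = (diag(sqrt(r)) - r sqrt(r)^T) / sqrt(n)`` satisfies
    ``C @ C.T = (diag(r) - r r^T) / n``, the multinomial covariance.
    """
    if dist.n is None:
        raise ValueError("sample size required")
    r = dist.probs
    s = np.sqrt(r)
    return (np.diag(s) - np.outer(r, s)) / np.sqrt(dist.n)
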