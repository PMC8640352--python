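"""Data-driven bandwidth selection for kernel equating.

Six selectors are provided, all operating on a (typically presmoothed)
:class:`~keq.core.DiscreteScoreDistribution`:

``penalty``
    Minimizes the squared distance between the score probabilities and
    the continuized density at the score points, plus ``kappa`` times a
    count of sign changes of the density derivative near score points
    (penalizing wiggly densities).
``srt``
    Silverman's rule of thumb adapted to the moment-preserving
    continuization: the closed form ``h = 9 sigma / sqrt(100 n^{2/5} - 81)``,
    equivalent to setting the effective kernel scale ``a h`` to the
    classical ``0.9 sigma n^{-1/5}``.
``ds``
    Double smoothing: a large pilot bandwidth ``q`` produces a pilot
    density whose values at the score points replace the probabilities as
    mixture weights; the criterion compares the resulting estimate to the
    observed probabilities at score points and to the pilot density at
    midpoints.
``licv``
    Likelihood cross-validation: repeated random half-splits of the test
    takers; for each split the bandwidth maximizing a Poisson likelihood
    of the second half's frequencies under the first half's density is
    recorded, and the median over splits is returned.
``lcv``
    Leave-one-out cross-validation of the density at the score points
    (one score point's probability mass removed at a time, shrinkage and
    mean kept at their full-sample values).
``plcv``
    LCV plus the same sign-change penalty as the penalty method.

Grid-based selectors minimize their criterion by a dense grid search
(coarse step then a 0.001 refinement), which is robust to the step
discontinuities the penalty term introduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DiscreteScoreDistribution

__all__ = [
    "BandwidthSelection",
    "penalty_term",
    "select_penalty",
    "select_srt",
    "select_ds",
    "select_licv",
    "select_lcv",
    "select_plcv",
    "select_bandwidth",
    "METHODS",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)
DEFAULT_RANGE = (0.01, 30.0)


@dataclass(frozen=True)
class BandwidthSelection:
    method: str
    h: float
    criterion_value: float
    diagnostics: dict = field(default_factory=dict)


def _mixture_values(x_scores, weights, mu, sigma2, hs, t, deriv=False,
                    drop_own=False, dtype=np.float64):
    """Gaussian-mixture density (or its derivative) on a grid of bandwidths.

    Returns an ``(len(hs), len(t))`` array.  ``drop_own`` removes the
    ``j``-th component at evaluation point ``j`` (requires ``t`` to be the
    score grid itself) for the leave-one-out criteria.  ``dtype=float32``
    is accurate enough for locating a criterion's basin on a coarse grid
    and halves the cost of the exponentials.
    """
    x = np.asarray(x_scores, dtype=dtype)
    w = np.asarray(weights, dtype=dtype)
    hs = np.atleast_1d(np.asarray(hs, dtype=dtype))
    t = np.asarray(t, dtype=dtype)
    mu = dtype(mu)
    sigma2 = dtype(sigma2)
    out = np.empty((hs.size, t.size), dtype=dtype)
    chunk = max(1, int(4e6 // (x.size * t.size)) or 1)
    for start in range(0, hs.size, chunk):
        h = hs[start:start + chunk][:, None, None]          # (c,1,1)
        a = np.sqrt(sigma2 / (sigma2 + h * h))
        ah = a * h
        z = (t[None, :, None] - a * x[None, None, :]
             - (1.0 - a) * mu) / ah                         # (c,M,J)
        dens = np.exp(-0.5 * z * z) / (_SQRT2PI * ah)
        if deriv:
            dens = -z * dens / ah
        if drop_own:
            contrib = np.einsum("cmj,j->cm", dens, w)
            own = np.take_along_axis(
                dens, np.arange(t.size)[None, :, None], axis=2)[:, :, 0]
            out[start:start + chunk] = contrib - w * own
        else:
            out[start:start + chunk] = np.einsum("cmj,j->cm", dens, w)
    return out


def _penalty_counts(dist: DiscreteScoreDistribution, hs, w: float,
                    flip: str = "dip", dtype=np.float64) -> np.ndarray:
    """Number of score points where the density derivative flips sign
    between ``x_j - w`` and ``x_j + w``, per bandwidth.

    ``flip="dip"`` counts U-shapes only (derivative negative on the left,
    positive on the right — a valley at the score point), the smoothness
    penalty of the penalty method's source literature: an undersmoothed
    density has valleys at low-probability score points, and the count
    returns to zero once the bandwidth is large enough.  ``flip="both"``
    additionally counts local maxima; note a unimodal density's genuine
    mode then keeps triggering one count at the nearest score point for
    every bandwidth, so the count never settles at zero.
    """
    x, r = dist.scores, dist.probs
    mu, s2 = dist.mean, dist.var
    d_lo = _mixture_values(x, r, mu, s2, hs, x - w, deriv=True, dtype=dtype)
    d_hi = _mixture_values(x, r, mu, s2, hs, x + w, deriv=True, dtype=dtype)
    flips = (d_lo < 0) & (d_hi > 0)
    if flip == "both":
        flips = flips | ((d_lo > 0) & (d_hi < 0))
    elif flip != "dip":
        raise ValueError("flip must be 'dip' or 'both'")
    return flips.sum(axis=1)


def penalty_term(dist: DiscreteScoreDistribution, h: float, w: float = 0.25,
                 flip: str = "dip") -> int:
    """Sign-change penalty count ``sum_j A_j`` at a single bandwidth."""
    if w <= 0 or h <= 0:
        raise ValueError("h and w must be positive")
    return int(_penalty_counts(dist, [h], w, flip)[0])


def _grid_minimize(criterion, h_range, coarse_step=0.05, fine_step=0.001):
    """Two-stage dense grid minimization of a vectorized criterion.

    ``criterion`` maps an array of bandwidths to an array of values.
    Agrees with an exhaustive ``fine_step`` grid search within one step
    whenever the objective's basins are wider than ``coarse_step``.
    """
    lo, hi = h_range
    coarse = np.arange(lo, hi + coarse_step / 2, coarse_step)
    vals = criterion(coarse, np.float32)
    h0 = coarse[int(np.argmin(vals))]
    fine = np.arange(max(lo, h0 - coarse_step), min(hi, h0 + coarse_step)
                     + fine_step / 2, fine_step)
    fvals = criterion(fine, np.float64)
    i = int(np.argmin(fvals))
    return float(fine[i]), float(fvals[i])


def _pen_criterion(dist, kappa, w, hs, flip="dip", dtype=np.float64):
    f = _mixture_values(dist.scores, dist.probs, dist.mean, dist.var, hs,
                        dist.scores, dtype=dtype)
    sq = ((dist.probs[None, :] - f) ** 2).sum(axis=1)
    if kappa != 0:
        sq = sq + kappa * _penalty_counts(dist, hs, w, flip, dtype=dtype)
    return sq


def select_penalty(dist: DiscreteScoreDistribution, kappa: float = 1.0,
                   w: float = 0.25, h_range=DEFAULT_RANGE,
                   flip: str = "dip") -> BandwidthSelection:
    """Penalty-method bandwidth: minimize
    ``sum_j (r_j - f_h(x_j))^2 + kappa * sum_j A_j``."""
    h, val = _grid_minimize(
        lambda hs, dt=np.float64: _pen_criterion(dist, kappa, w, hs, flip, dt),
        h_range)
    return BandwidthSelection("penalty", h, val,
                              {"kappa": kappa, "w": w,
                               "penalty_count": penalty_term(dist, h, w, flip)})


def select_srt(dist: DiscreteScoreDistribution) -> BandwidthSelection:
    """Silverman's rule of thumb, adjusted for the shrinkage factor.

    Solves ``a(h) * h = 0.9 * sigma * n^{-1/5}`` in closed form, giving
    ``h = 9 sigma / sqrt(100 n^{2/5} - 81)``.
    """
    if dist.n is None:
        raise ValueError("sample size n is required for SRT")
    sigma = dist.sd
    if sigma <= 0:
        raise ValueError("degenerate distribution")
    denom = 100.0 * dist.n ** 0.4 - 81.0
    if denom <= 0:
        raise ValueError("sample size too small for SRT")
    h = 9.0 * sigma / np.sqrt(denom)
    return BandwidthSelection("srt", float(h), float("nan"),
                              {"sigma": sigma, "n": dist.n})


def _ds_criterion(dist, q, hs, dtype=np.float64):
    x, r = dist.scores, dist.probs
    mu, s2 = dist.mean, dist.var
    # grid of score points and midpoints: x_1, x_1 + .5, x_2, ..., x_J
    star = np.empty(2 * x.size - 1)
    star[0::2] = x
    star[1::2] = (x[:-1] + x[1:]) / 2.0
    pilot_star = _mixture_values(x, r, mu, s2, [q], star)[0].astype(dtype)
    pilot_scores = pilot_star[0::2]
    weights = pilot_scores / pilot_scores.sum()
    target = pilot_star.copy()
    target[0::2] = r  # observed probabilities at the actual score points
    f_star = _mixture_values(x, weights, mu, s2, hs, star, dtype=dtype)
    return ((target[None, :] - f_star) ** 2).sum(axis=1)


def select_ds(dist: DiscreteScoreDistribution, q: float | None = None,
              h_range=DEFAULT_RANGE) -> BandwidthSelection:
    """Double-smoothing bandwidth with pilot bandwidth ``q``.

    ``q`` defaults to three times the Silverman rule-of-thumb value (a
    deliberately large pilot); the pilot density's values at the score
    points, renormalized, act as mixture weights of the double-smoothed
    estimate.
    """
    if q is None:
        q = 3.0 * select_srt(dist).h
    if q <= 0:
        raise ValueError("pilot bandwidth must be positive")
    h, val = _grid_minimize(
        lambda hs, dt=np.float64: _ds_criterion(dist, q, hs, dtype=dt), h_range)
    return BandwidthSelection("ds", h, val, {"pilot": float(q)})


def _lcv_criterion(dist, hs, dtype=np.float64):
    loo = _mixture_values(dist.scores, dist.probs, dist.mean, dist.var, hs,
                          dist.scores, drop_own=True, dtype=dtype)
    return ((dist.probs[None, :] - loo) ** 2).mean(axis=1)


def select_lcv(dist: DiscreteScoreDistribution,
               h_range=DEFAULT_RANGE) -> BandwidthSelection:
    """Leave-one-out cross-validation bandwidth.

    The left-out density ``f^{-j}`` omits component ``j`` without
    renormalizing the remaining probabilities; the shrinkage factor and
    mean stay at their full-sample values.
    """
    if dist.scores.size < 2:
        raise ValueError("need at least two score points")
    h, val = _grid_minimize(
        lambda hs, dt=np.float64: _lcv_criterion(dist, hs, dtype=dt), h_range)
    return BandwidthSelection("lcv", h, val)


def select_plcv(dist: DiscreteScoreDistribution, kappa: float = 1.0,
                w: float = 0.25, h_range=DEFAULT_RANGE,
                flip: str = "dip") -> BandwidthSelection:
    """Penalized LCV: the LCV criterion plus ``kappa * sum_j A_j``."""
    if dist.scores.size < 2:
        raise ValueError("need at least two score points")

    def crit(hs, dt=np.float64):
        vals = _lcv_criterion(dist, hs, dtype=dt)
        if kappa != 0:
            vals = vals + kappa * _penalty_counts(dist, hs, w, flip, dtype=dt)
        return vals

    h, val = _grid_minimize(crit, h_range)
    return BandwidthSelection("plcv", h, val,
                              {"kappa": kappa, "w": w,
                               "penalty_count": penalty_term(dist, h, w, flip)})


def select_licv(dist: DiscreteScoreDistribution, grid=None,
                n_repeats: int = 1000, seed=None,
                presmooth_degree: int | None = None) -> BandwidthSelection:
    """Likelihood cross-validation over repeated random half-splits.

    Requires raw counts (individual test takers are resampled).  For each
    repeat the test takers are split into halves of sizes ceil(n/2) and
    floor(n/2); the first half yields the kernel density, the second
    half's frequencies enter a Poisson likelihood with intensities
    ``N1 * f_h(x_j)``, maximized over the bandwidth grid.  The median of
    the per-repeat maximizers is returned.

    ``presmooth_degree`` fits a univariate log-linear model of that
    degree to the training half before continuizing, following the
    method's source procedure in which each subsample is presmoothed; the
    raw empirical training density (``None``) tends to push the Poisson
    likelihood toward ever larger bandwidths and pins the maximizer to
    the top of the grid.
    """
    if dist.counts is None:
        raise ValueError("LiCV needs raw counts")
    counts = np.round(dist.counts).astype(int)
    n = int(counts.sum())
    if n < 2:
        raise ValueError("need at least two test takers")
    if grid is None:
        grid = np.arange(0.01, 5.0 + 0.005, 0.01)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty bandwidth grid")
    rng = np.random.default_rng(seed)
    x = dist.scores
    individuals = np.repeat(np.arange(x.size), counts)
    n1 = (n + 1) // 2
    picks = np.empty(n_repeats)
    for rep in range(n_repeats):
        for _ in range(100):
            perm = rng.permutation(individuals)
            half1 = np.bincount(perm[:n1], minlength=x.size).astype(float)
            r1 = half1 / n1
            mu1 = x @ r1
            s21 = ((x - mu1) ** 2) @ r1
            if s21 > 0:
                break
        else:
            raise ValueError("could not form a non-degenerate half-split")
        if presmooth_degree is not None:
            from .presmoothing import FittingError, fit_loglinear_univariate
            try:
                r1 = fit_loglinear_univariate(x, half1, presmooth_degree).fitted_probs
                mu1 = x @ r1
                s21 = ((x - mu1) ** 2) @ r1
            except FittingError:
                pass  # keep the raw empirical half on rare non-convergence
        half2 = np.bincount(perm[n1:], minlength=x.size).astype(float)

        def loglik_at(h_subset):
            f1 = _mixture_values(x, r1, mu1, s21, h_subset, x,
                                 dtype=np.float32)          # (H, J)
            lam = np.maximum(n1 * f1, np.float32(1e-30))
            return (half2[None, :] * np.log(lam) - lam).sum(axis=1)

        if grid.size > 50:
            # coarse pass on every 5th grid point, then the local window
            stride = 5
            i0 = stride * int(np.argmax(loglik_at(grid[::stride])))
            window = slice(max(0, i0 - stride - 1), i0 + stride + 2)
            sub = grid[window]
            picks[rep] = sub[int(np.argmax(loglik_at(sub)))]
        else:
            picks[rep] = grid[int(np.argmax(loglik_at(grid)))]
    h = float(np.median(picks))
    return BandwidthSelection("licv", h, float("nan"),
                              {"n_repeats": n_repeats,
                               "presmooth_degree": presmooth_degree,
                               "bandwidth_sample_sd": float(np.std(picks)),
                               "grid": (float(grid[0]), float(grid[-1]))})


METHODS = ("penalty", "srt", "ds", "licv", "lcv", "plcv")


def select_bandwidth(dist: DiscreteScoreDistribution, method: str,
                     **kwargs) -> BandwidthSelection:
    """Dispatch to one of the six selectors by name."""
    try:
        fn = {"penalty": select_penalty, "srt": select_srt, "ds": select_ds,
              "licv": select_licv, "lcv": select_lcv, "plcv": select_plcv}[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return fn(dist, **kwargs)
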