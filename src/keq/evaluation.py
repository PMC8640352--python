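"""Accuracy and precision measures for kernel equating.

* PRE — percent relative error of the moments of the equated scores
  against the reference form's moments.
* MSE / SE — Monte-Carlo accuracy of the equated mean and per-score
  variability over simulation replicates.
* SEE — the delta-method standard error of equating
  ``SEE_Y(x) = || J_phi J_DF C ||`` combining the Jacobian of the
  equating transform, the design-function Jacobian and the covariance
  factor of the presmoothed probabilities; and its nonparametric
  bootstrap counterpart.
* DTM — "difference that matters" flags (equated-score discrepancies
  exceeding half a raw-score unit).

Bandwidths are treated as fixed constants in the analytical SEE; the
bootstrap re-selects them per resample and so includes their sampling
variability.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .bandwidth import select_bandwidth
from .core import ContinuizedDistribution, DiscreteScoreDistribution
from .equating import EquatingResult, equate
from .presmoothing import (LoglinearFit, cov_factor, fit_loglinear_univariate,
                           multinomial_cov_factor)

__all__ = [
    "pre_moments",
    "mse_of_mean",
    "se_per_score",
    "see_analytical",
    "see_analytical_eg",
    "see_analytical_neat",
    "see_bootstrap",
    "dtm_compare",
    "stacked_cov_factor_eg",
    "stacked_cov_factor_neat",
]


def pre_moments(result: EquatingResult, r, y_scores, s, p_max: int = 10) -> np.ndarray:
    """Percent relative error of moments 1..p_max of the equated scores.

    ``PRE(p) = 100 (mu_p(phi(X)) - mu_p(Y)) / mu_p(Y)`` with
    ``mu_p(phi(X)) = sum_j phi(x_j)^p r_j`` and
    ``mu_p(Y) = sum_k y_k^p s_k``.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    y = np.asarray(y_scores, dtype=float)
    out = np.empty(p_max)
    for p in range(1, p_max + 1):
        mu_y = (y**p) @ s
        if mu_y == 0:
            raise ZeroDivisionError(f"moment {p} of Y is zero; PRE undefined")
        out[p - 1] = 100.0 * ((result.equated**p) @ r - mu_y) / mu_y
    return out


def mse_of_mean(replicate_means, mu_true: float) -> float:
    """Squared bias of the replicate means plus their (G-1)-corrected variance."""
    m = np.asarray(replicate_means, dtype=float)
    if m.size < 2:
        raise ValueError("need at least two replicates")
    return float((m.mean() - mu_true) ** 2 + m.var(ddof=1))


def se_per_score(replicate_curves) -> np.ndarray:
    """Per-score corrected sample standard deviation over replicate curves."""
    curves = np.asarray(replicate_curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need a (G, J) array with G >= 2")
    return curves.std(axis=0, ddof=1)


def dtm_compare(curve_a, curve_b, threshold: float = 0.5) -> np.ndarray:
    """Flags where two equated-score curves differ by more than a DTM."""
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must share the score grid")
    return np.abs(a - b) > threshold


# --------------------------------------------------------------------------
# Analytical SEE

def _cdf_jacobian(cd: ContinuizedDistribution, x_eval) -> np.ndarray:
    """``d F_h(x; r) / d r`` at each evaluation point, shape (M, J).

    The shrinkage factor and mean both depend on ``r``; writing
    ``z_j(x) = (x - mu)/(a h) + (mu - x_j)/h`` shows that
    ``d z_j / d r_m`` does not depend on ``j``, so the derivative
    collapses to ``Phi(z_m) + D_m(x) * a h * f_h(x)``.
    """
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))
    xs = cd.base.scores
    a, h, mu, s2 = cd.a, cd.h, cd.mu, cd.sigma2
    z = cd._z(x_eval)                           # (M, J)
    phi_terms = stats.norm.cdf(z)
    f = cd.pdf(x_eval)                          # (M,)
    dsig2 = xs**2 - 2.0 * mu * xs               # d sigma^2 / d r_m, (J,)
    common = -(x_eval - mu) * h / (2.0 * a**3 * (s2 + h * h) ** 2)  # (M,)
    D = (xs / h) * (1.0 - 1.0 / a) + np.outer(common, dsig2)        # (M, J)
    return phi_terms + (a * h) * f[:, None] * D


def see_analytical(r_dist: DiscreteScoreDistribution,
                   s_dist: DiscreteScoreDistribution,
                   h_x: float, h_y: float,
                   c_stacked: np.ndarray) -> EquatingResult:
    """Delta-method SEE given the covariance factor of the stacked (r, s).

    ``c_stacked`` has ``J + K`` rows; ``c_stacked @ c_stacked.T`` is the
    covariance of the stacked probability vector after the design
    function (for EG a block-diagonal of the two forms' factors, for
    NEAT PSE the design-function Jacobian times the joint-table factors).
    """
    fx = ContinuizedDistribution(r_dist, h_x)
    gy = ContinuizedDistribution(s_dist, h_y)
    res = equate(r_dist, s_dist, h_x, h_y)
    g_at_phi = gy.pdf(res.equated)
    g_safe = np.maximum(g_at_phi, 1e-12)        # tail-instability guard
    jac_F = _cdf_jacobian(fx, r_dist.scores)    # (J, J)
    jac_G = _cdf_jacobian(gy, res.equated)      # (J, K)
    J = r_dist.scores.size
    K = s_dist.scores.size
    j_phi = np.empty((J, J + K))
    j_phi[:, :J] = jac_F / g_safe[:, None]
    j_phi[:, J:] = -jac_G / g_safe[:, None]
    M = j_phi @ c_stacked
    see = np.sqrt((M * M).sum(axis=1))
    return EquatingResult(x_scores=res.x_scores, equated=res.equated,
                          h_x=res.h_x, h_y=res.h_y, see=see)


def _factor_of(fit) -> np.ndarray:
    if isinstance(fit, LoglinearFit):
        return cov_factor(fit)
    if isinstance(fit, DiscreteScoreDistribution):
        return multinomial_cov_factor(fit)
    raise TypeError("expected a LoglinearFit or a DiscreteScoreDistribution")


def stacked_cov_factor_eg(fit_x, fit_y) -> np.ndarray:
    """Block-diagonal covariance factor for the EG design (identity DF).

    Accepts log-linear fits, or raw distributions for the
    no-presmoothing (multinomial) case.
    """
    cx = _factor_of(fit_x)
    cy = _factor_of(fit_y)
    out = np.zeros((cx.shape[0] + cy.shape[0], cx.shape[1] + cy.shape[1]))
    out[:cx.shape[0], :cx.shape[1]] = cx
    out[cx.shape[0]:, cx.shape[1]:] = cy
    return out


def _pse_jacobian(p_probs: np.ndarray, q_probs: np.ndarray, weight: float):
    """Jacobians of the PSE probabilities w.r.t. the flattened joint tables.

    Returns ``(dr_dp, dr_dq, ds_dp, ds_dq)`` with shapes
    ``(J, J*L), (J, K*L), (K, J*L), (K, K*L)``.
    """
    J, L = p_probs.shape
    K = q_probs.shape[0]
    pa = p_probs.sum(axis=0)
    qa = q_probs.sum(axis=0)
    w = weight
    t = w * pa + (1.0 - w) * qa
    # d r_j / d p_{j'l'} = delta_{jj'} t_l'/pa_l' + p_{jl'}(w pa_l' - t_l')/pa_l'^2
    dr_dp = np.zeros((J, J, L))
    diag = t / pa
    for l in range(L):
        dr_dp[:, :, l] = np.outer(p_probs[:, l], np.ones(J)) * (
            (w * pa[l] - t[l]) / pa[l] ** 2)
        dr_dp[np.arange(J), np.arange(J), l] += diag[l]
    # d r_j / d q_{k'l'} = (1-w) p_{jl'} / pa_l'   (independent of k')
    dr_dq = np.repeat((1.0 - w) * (p_probs / pa)[:, None, :], K, axis=1)
    # symmetric expressions for s
    ds_dq = np.zeros((K, K, L))
    diag_q = t / qa
    for l in range(L):
        ds_dq[:, :, l] = np.outer(q_probs[:, l], np.ones(K)) * (
            ((1.0 - w) * qa[l] - t[l]) / qa[l] ** 2)
        ds_dq[np.arange(K), np.arange(K), l] += diag_q[l]
    ds_dp = np.repeat(w * (q_probs / qa)[:, None, :], J, axis=1)
    return (dr_dp.reshape(J, J * L), dr_dq.reshape(J, K * L),
            ds_dp.reshape(K, J * L), ds_dq.reshape(K, K * L))


def stacked_cov_factor_neat(fit_p: LoglinearFit, fit_q: LoglinearFit,
                            weight: float) -> np.ndarray:
    """Design-function-propagated covariance factor for NEAT PSE."""
    p_probs = fit_p.fitted_probs
    q_probs = fit_q.fitted_probs
    dr_dp, dr_dq, ds_dp, ds_dq = _pse_jacobian(p_probs, q_probs, weight)
    cp = cov_factor(fit_p)
    cq = cov_factor(fit_q)
    J, K = p_probs.shape[0], q_probs.shape[0]
    out = np.zeros((J + K, cp.shape[1] + cq.shape[1]))
    out[:J, :cp.shape[1]] = dr_dp @ cp
    out[:J, cp.shape[1]:] = dr_dq @ cq
    out[J:, :cp.shape[1]] = ds_dp @ cp
    out[J:, cp.shape[1]:] = ds_dq @ cq
    return out


def see_analytical_eg(fit_x, fit_y, h_x: float, h_y: float) -> EquatingResult:
    """Analytical SEE under the EG design (identity design function)."""
    r_dist = fit_x.distribution() if isinstance(fit_x, LoglinearFit) else fit_x
    s_dist = fit_y.distribution() if isinstance(fit_y, LoglinearFit) else fit_y
    return see_analytical(r_dist, s_dist, h_x, h_y,
                          stacked_cov_factor_eg(fit_x, fit_y))


def see_analytical_neat(fit_p: LoglinearFit, fit_q: LoglinearFit, weight: float,
                        h_x: float, h_y: float) -> EquatingResult:
    """Analytical SEE under the NEAT design with post-stratification."""
    from .equating import post_stratify

    r, s = post_stratify(fit_p.table(), fit_q.table(), weight)
    r_dist = DiscreteScoreDistribution(fit_p.x_scores, r, n=fit_p.n)
    s_dist = DiscreteScoreDistribution(fit_q.x_scores, s, n=fit_q.n)
    return see_analytical(r_dist, s_dist, h_x, h_y,
                          stacked_cov_factor_neat(fit_p, fit_q, weight))


def see_bootstrap(x_dist: DiscreteScoreDistribution,
                  y_dist: DiscreteScoreDistribution,
                  bandwidth_method: str = "penalty",
                  presmooth_degree: int | None = None,
                  B: int = 1000, seed=None,
                  bandwidth_kwargs: dict | None = None) -> np.ndarray:
    """Bootstrap SEE under the EG design.

    Draws ``B`` nonparametric resamples of the test takers of each form
    (multinomial over the empirical probabilities), re-runs the full
    pipeline — optional presmoothing, bandwidth selection, equating — on
    each, and returns the per-score corrected standard deviation of the
    equated curves.  Unlike the analytical SEE this captures bandwidth
    variability.
    """
    if B < 2:
        raise ValueError("need at least two bootstrap draws")
    for d in (x_dist, y_dist):
        if d.counts is None or d.n is None:
            raise ValueError("bootstrap needs raw counts")
        if d.var <= 0:
            raise ValueError("degenerate distribution")
    rng = np.random.default_rng(seed)
    kwargs = dict(bandwidth_kwargs or {})
    curves = np.empty((B, x_dist.scores.size))
    for b in range(B):
        dists = []
        for d in (x_dist, y_dist):
            counts = rng.multinomial(d.n, d.counts / d.counts.sum())
            boot = DiscreteScoreDistribution.from_counts(d.scores, counts)
            if presmooth_degree is not None:
                fit = fit_loglinear_univariate(d.scores, counts, presmooth_degree)
                boot = boot.with_probs(fit.fitted_probs)
            dists.append(boot)
        bx, by = dists
        kw = dict(kwargs)
        if bandwidth_method == "licv":
            kw.setdefault("seed", rng.integers(2**31 - 1))
        h_x = select_bandwidth(bx, bandwidth_method, **kw).h
        h_y = select_bandwidth(by, bandwidth_method, **kw).h
        curves[b] = equate(bx, by, h_x, h_y).equated
    return se_per_score(curves)
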