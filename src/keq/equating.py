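"""Design functions and the kernel equipercentile transformation.

The equipercentile transform equating form X to form Y is

    phi_Y(x) = G^{-1}(F(x)),

with ``F`` and ``G`` the target-population CDFs of the two forms.  Kernel
equating estimates it by continuizing the (presmoothed) discrete score
distributions ``r`` and ``s``:

    phi_hat_Y(x) = G_hY^{-1}(F_hX(x)).

The *design function* maps the presmoothed data onto ``(r, s)`` on the
target population ``T``:

* EG (equivalent groups): the identity — each group's marginal is already
  a ``T`` estimate.
* NEAT with post-stratification (PSE): ``T = w P + (1 - w) Q`` and the
  conditional distributions given the anchor are re-weighted,

    r_j(T) = sum_l Pr(X = x_j | A = a_l, P)
                   [w Pr(A = a_l | P) + (1 - w) Pr(A = a_l | Q)],

  and symmetrically for ``s`` using Q's conditionals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (BivariateScoreTable, ContinuizedDistribution,
                   DiscreteScoreDistribution, inverse_cdf)

__all__ = ["DesignSpec", "EquatingResult", "design_function",
           "post_stratify", "equate"]


@dataclass(frozen=True)
class DesignSpec:
    """Data-collection design: ``"eg"`` or ``"neat_pse"`` with target weight."""

    design: str = "eg"
    weight: float = 0.5

    def __post_init__(self) -> None:
        if self.design not in ("eg", "neat_pse"):
            raise ValueError("design must be 'eg' or 'neat_pse'")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")


@dataclass(frozen=True)
class EquatingResult:
    x_scores: np.ndarray
    equated: np.ndarray
    h_x: float
    h_y: float
    see: np.ndarray | None = None
    method: str = ""


def post_stratify(p_table: BivariateScoreTable, q_table: BivariateScoreTable,
                  weight: float) -> tuple[np.ndarray, np.ndarray]:
    """PSE score probabilities ``(r(T), s(T))`` from the two joint tables.

    ``p_table`` holds (X, A) on population P, ``q_table`` (Y, A) on Q;
    both must share the anchor grid.  Probabilities must be strictly
    positive on the anchor margin (guaranteed by log-linear presmoothing).
    """
    if not np.array_equal(p_table.a_scores, q_table.a_scores):
        raise ValueError("anchor score grids do not match")
    pa = p_table.probs.sum(axis=0)
    qa = q_table.probs.sum(axis=0)
    if np.any(pa <= 0) or np.any(qa <= 0):
        raise ValueError("zero anchor-marginal probability in a conditioning "
                         "population; presmooth the tables first")
    t = weight * pa + (1.0 - weight) * qa
    r = (p_table.probs / pa) @ t
    s = (q_table.probs / qa) @ t
    return r, s


def design_function(spec: DesignSpec, p_data, q_data):
    """Map presmoothed data to ``(r, s)`` distributions on ``T``.

    EG: ``p_data``/``q_data`` are univariate distributions, passed through.
    NEAT PSE: bivariate tables, post-stratified with ``spec.weight``.
    Sample sizes are carried along for bandwidth selection.
    """
    if spec.design == "eg":
        if not isinstance(p_data, DiscreteScoreDistribution):
            raise TypeError("EG design expects univariate distributions")
        return p_data, q_data
    r, s = post_stratify(p_data, q_data, spec.weight)
    r_dist = DiscreteScoreDistribution(p_data.x_scores, r,
                                       counts=None if p_data.counts is None
                                       else p_data.counts.sum(axis=1),
                                       n=p_data.n)
    s_dist = DiscreteScoreDistribution(q_data.x_scores, s,
                                       counts=None if q_data.counts is None
                                       else q_data.counts.sum(axis=1),
                                       n=q_data.n)
    return r_dist, s_dist


def equate(r_dist: DiscreteScoreDistribution, s_dist: DiscreteScoreDistribution,
           h_x: float, h_y: float, method: str = "") -> EquatingResult:
    """Kernel equipercentile equating of form X onto form Y's scale."""
    fx = ContinuizedDistribution(r_dist, h_x)
    gy = ContinuizedDistribution(s_dist, h_y)
    p = fx.cdf(r_dist.scores)
    # strictly inside (0,1) for h > 0, but guard against underflow at tails
    eps = 1e-15
    p = np.clip(p, eps, 1.0 - eps)
    equated = inverse_cdf(gy, p)
    return EquatingResult(x_scores=r_dist.scores, equated=equated,
                          h_x=float(h_x), h_y=float(h_y), method=method)
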