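"""Monte-Carlo study of bandwidth selection in kernel equating.

The data-generating process mimics number-correct scoring on a
standardized test:

1.  *Truth.*  Latent proportional-correct abilities are drawn from a
    beta distribution (or beta mixture for bimodal data); for the NEAT
    design the test and anchor abilities are coupled through a Gaussian
    copula with correlation 0.75.  Scores are the latents times the test
    length, rounded to the integer grid.  A log-linear model fitted to
    one such sample (AIC-guided for EG, BIC for NEAT) defines the *true*
    score probabilities — smooth, strictly positive, and realistic.
    This step runs once per scenario.
2.  *Replicates.*  Each replicate draws multinomial frequencies from the
    truth, presmooths them with the same log-linear design, applies the
    design function (identity for EG; post-stratification with target
    weight 0.5 for NEAT), selects bandwidths with each method under
    study, and equates.

Population Q's form score is shifted five units (clamped to the grid) so
the two forms genuinely differ and the identity is never the true
equating function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from . import bandwidth as bw
from .core import BivariateScoreTable, DiscreteScoreDistribution
from .equating import EquatingResult, equate, post_stratify
from .evaluation import mse_of_mean, pre_moments, se_per_score
from .presmoothing import (fit_loglinear_bivariate, fit_loglinear_univariate,
                           select_model, FittingError)

__all__ = ["SimulationScenario", "Truth", "SimulationSummary",
           "generate_truth", "sample_replicate", "run_scenario",
           "BETA_SHAPES"]

BETA_SHAPES = {
    "symmetric": ((5.0, 5.0),),
    "neg_skew": ((5.0, 2.0),),
    "pos_skew": ((2.0, 5.0),),
    "bimodal": ((25.0, 15.0), (15.0, 25.0)),
}

# Log-linear designs stated for each scenario: EG univariate degrees;
# NEAT (marginal degree, anchor degree, cross-moment set).
EG_DEGREES = {"symmetric": 2, "neg_skew": 3, "pos_skew": 3, "bimodal": 3}
NEAT_DESIGNS = {
    "symmetric": (4, 4, ((1, 1), (2, 2))),
    "neg_skew": (4, 4, ((1, 1), (2, 2))),
    "pos_skew": (2, 2, ((1, 1),)),
    "bimodal": (2, 2, ((1, 1),)),
}


@dataclass(frozen=True)
class SimulationScenario:
    design: str = "eg"                # "eg" | "neat"
    shape: str = "symmetric"
    n: int = 1000                     # test takers per group
    j_minus_1: int = 80               # test length (score grid 0..J-1)
    l_minus_1: int = 20               # anchor length (NEAT)
    rho: float = 0.75                 # copula correlation (NEAT)
    q_shift: int = 5                  # form-score shift of population Q (NEAT)
    G: int = 1000                     # replications
    weight: float = 0.5               # PSE target-population weight
    cross_mode: str = "second_order"  # "(1,1),(2,2)" vs all first/second orders

    def __post_init__(self) -> None:
        if self.design not in ("eg", "neat"):
            raise ValueError("design must be 'eg' or 'neat'")
        if self.shape not in BETA_SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")

    @property
    def x_scores(self) -> np.ndarray:
        return np.arange(self.j_minus_1 + 1, dtype=float)

    @property
    def a_scores(self) -> np.ndarray:
        return np.arange(self.l_minus_1 + 1, dtype=float)

    def neat_design(self):
        dx, da, cross = NEAT_DESIGNS[self.shape]
        if self.cross_mode == "all_first_second" and cross == ((1, 1), (2, 2)):
            cross = ((1, 1), (1, 2), (2, 1))
        return dx, da, cross


@dataclass(frozen=True)
class Truth:
    """True score probabilities and the presmoothing designs that made them."""

    scenario: SimulationScenario
    x: DiscreteScoreDistribution | BivariateScoreTable
    y: DiscreteScoreDistribution | BivariateScoreTable
    design_x: dict
    design_y: dict

    def target_probs(self) -> tuple[np.ndarray, np.ndarray]:
        """True (r, s) on the target population."""
        if self.scenario.design == "eg":
            return self.x.probs, self.y.probs
        return post_stratify(self.x, self.y, self.scenario.weight)


def _mixture_rvs(components, rng, size):
    if len(components) == 1:
        a, b = components[0]
        return rng.beta(a, b, size=size)
    which = rng.integers(len(components), size=size)
    out = np.empty(size)
    for i, (a, b) in enumerate(components):
        mask = which == i
        out[mask] = rng.beta(a, b, size=int(mask.sum()))
    return out


def _mixture_ppf(components, u):
    """Quantile function of an equal-weight beta mixture (numeric for >1)."""
    if len(components) == 1:
        a, b = components[0]
        return stats.beta.ppf(u, a, b)

    def cdf(t):
        return np.mean([stats.beta.cdf(t, a, b) for a, b in components], axis=0)

    out = np.empty_like(u)
    for i, ui in np.ndenumerate(u):
        out[i] = optimize.brentq(lambda t: cdf(t) - ui, 0.0, 1.0, xtol=1e-12)
    return out


def _copula_pair(components, rho, rng, size):
    """(U, V) with beta(-mixture) marginals and Gaussian-copula dependence."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=size)
    u01 = stats.norm.cdf(z)
    # guard against exact 0/1 from floating-point underflow
    u01 = np.clip(u01, 1e-12, 1.0 - 1e-12)
    return _mixture_ppf(components, u01[:, 0]), _mixture_ppf(components, u01[:, 1])


def _round_scores(u: np.ndarray, length: int) -> np.ndarray:
    return np.clip(np.rint(u * length).astype(int), 0, length)


def _tabulate_univariate(scores_int, j_max) -> np.ndarray:
    return np.bincount(scores_int, minlength=j_max + 1).astype(float)


def _tabulate_bivariate(x_int, a_int, j_max, l_max) -> np.ndarray:
    counts = np.zeros((j_max + 1, l_max + 1))
    np.add.at(counts, (x_int, a_int), 1.0)
    return counts


def _fit_truth_univariate(scenario, counts, use_ic):
    x = scenario.x_scores
    if use_ic:
        fit = select_model((x, counts), criterion="aic")
    else:
        fit = fit_loglinear_univariate(x, counts, EG_DEGREES[scenario.shape])
    return fit


def _fit_truth_bivariate(scenario, table, use_ic):
    if use_ic:
        return select_model(table, criterion="bic")
    return fit_loglinear_bivariate(table, *scenario.neat_design())


def generate_truth(scenario: SimulationScenario, truth_seed=None,
                   use_ic: bool = False, max_attempts: int = 10) -> Truth:
    """Draw one latent sample per form and smooth it into true probabilities.

    ``use_ic=True`` replaces the scenario's stated log-linear design with
    a full AIC (EG) / BIC (NEAT) model search.
    """
    rng = np.random.default_rng(truth_seed)
    comps = BETA_SHAPES[scenario.shape]
    for _ in range(max_attempts):
        try:
            if scenario.design == "eg":
                fits = []
                for _form in ("x", "y"):
                    u = _mixture_rvs(comps, rng, scenario.n)
                    counts = _tabulate_univariate(
                        _round_scores(u, scenario.j_minus_1), scenario.j_minus_1)
                    fits.append(_fit_truth_univariate(scenario, counts, use_ic))
                fx, fy = fits
                return Truth(scenario,
                             DiscreteScoreDistribution(scenario.x_scores,
                                                       fx.fitted_probs,
                                                       n=scenario.n),
                             DiscreteScoreDistribution(scenario.x_scores,
                                                       fy.fitted_probs,
                                                       n=scenario.n),
                             fx.design, fy.design)
            tables = []
            for form, shift in (("x", 0), ("y", scenario.q_shift)):
                u, v = _copula_pair(comps, scenario.rho, rng, scenario.n)
                form_scores = _round_scores(u, scenario.j_minus_1)
                if shift:
                    form_scores = np.clip(form_scores + shift, 0,
                                          scenario.j_minus_1)
                anchor = _round_scores(v, scenario.l_minus_1)
                counts = _tabulate_bivariate(form_scores, anchor,
                                             scenario.j_minus_1,
                                             scenario.l_minus_1)
                table = BivariateScoreTable.from_counts(scenario.x_scores,
                                                        scenario.a_scores, counts)
                tables.append(_fit_truth_bivariate(scenario, table, use_ic))
            fp, fq = tables
            return Truth(scenario,
                         BivariateScoreTable(scenario.x_scores, scenario.a_scores,
                                             fp.fitted_probs, n=scenario.n),
                         BivariateScoreTable(scenario.x_scores, scenario.a_scores,
                                             fq.fitted_probs, n=scenario.n),
                         fp.design, fq.design)
        except FittingError:
            continue  # regenerate with fresh latents
    raise FittingError("truth generation failed repeatedly")


def sample_replicate(truth: Truth, seed=None):
    """One multinomial draw per population from the true probabilities."""
    rng = np.random.default_rng(seed)
    n = truth.scenario.n
    out = []
    for pop in (truth.x, truth.y):
        counts = rng.multinomial(n, pop.probs.ravel()).astype(float)
        if isinstance(pop, DiscreteScoreDistribution):
            out.append(DiscreteScoreDistribution.from_counts(pop.scores, counts))
        else:
            out.append(BivariateScoreTable.from_counts(
                pop.x_scores, pop.a_scores, counts.reshape(pop.probs.shape)))
    return tuple(out)


def _presmooth_replicate(truth: Truth, x_sample, y_sample):
    """Presmooth a replicate with the same designs as the truth."""
    sc = truth.scenario
    if sc.design == "eg":
        fx = fit_loglinear_univariate(x_sample.scores, x_sample.counts,
                                      truth.design_x["degree"])
        fy = fit_loglinear_univariate(y_sample.scores, y_sample.counts,
                                      truth.design_y["degree"])
        r = x_sample.with_probs(fx.fitted_probs)
        s = y_sample.with_probs(fy.fitted_probs)
        return r, s, fx, fy
    dx, da, cross = (truth.design_x["deg_x"], truth.design_x["deg_a"],
                     truth.design_x["cross"])
    fp = fit_loglinear_bivariate(x_sample, dx, da, cross)
    fq = fit_loglinear_bivariate(y_sample, dx, da, cross)
    r_probs, s_probs = post_stratify(fp.table(), fq.table(), sc.weight)
    r = DiscreteScoreDistribution(sc.x_scores, r_probs,
                                  counts=x_sample.counts.sum(axis=1), n=sc.n)
    s = DiscreteScoreDistribution(sc.x_scores, s_probs,
                                  counts=y_sample.counts.sum(axis=1), n=sc.n)
    return r, s, fp, fq


@dataclass
class SimulationSummary:
    scenario: SimulationScenario
    methods: tuple
    mu_y_true: float
    true_equating: np.ndarray
    mean_h_x: dict = field(default_factory=dict)
    var_h_x: dict = field(default_factory=dict)
    mean_h_y: dict = field(default_factory=dict)
    var_h_y: dict = field(default_factory=dict)
    mse: dict = field(default_factory=dict)
    se_curves: dict = field(default_factory=dict)
    mean_curves: dict = field(default_factory=dict)
    pre: dict = field(default_factory=dict)
    replicate_means: dict = field(default_factory=dict)
    h_x_samples: dict = field(default_factory=dict)
    n_failures: int = 0

    def dtm_matrix(self, threshold: float = 0.5) -> dict:
        """Pairwise counts of score points where mean curves differ by > DTM."""
        out = {}
        for m1 in self.mean_curves:
            for m2 in self.mean_curves:
                if m1 < m2:
                    diff = np.abs(self.mean_curves[m1] - self.mean_curves[m2])
                    out[(m1, m2)] = int((diff > threshold).sum())
        return out


def run_scenario(scenario: SimulationScenario, seed=None,
                 methods: Sequence[str] = bw.METHODS,
                 equate_methods: Sequence[str] | None = None,
                 licv_repeats: int = 1000,
                 licv_replicates: int | None = None,
                 licv_presmooth: int | None | str = "auto",
                 use_ic_truth: bool = False,
                 truth: Truth | None = None) -> SimulationSummary:
    """Run the full replicated experiment for one scenario.

    ``methods`` are run on the X-score distribution of every replicate;
    ``equate_methods`` (default: all of ``methods``) additionally select
    the Y bandwidth and carry out the equating, feeding the MSE/SE/PRE
    summaries.  ``licv_replicates`` caps the number of replicates on
    which the (costly) LiCV selector runs.
    """
    methods = tuple(methods)
    if equate_methods is None:
        equate_methods = methods
    equate_methods = tuple(equate_methods)
    if licv_presmooth == "auto":
        # univariate smoothing of the LiCV training half mirrors the
        # scenario's marginal moment design
        licv_presmooth = (NEAT_DESIGNS[scenario.shape][0]
                          if scenario.design == "neat"
                          else EG_DEGREES[scenario.shape])
    ss = np.random.SeedSequence(seed)
    truth_seed, rep_root = ss.spawn(2)
    if truth is None:
        truth = generate_truth(scenario, truth_seed, use_ic=use_ic_truth)
    r_true, s_true = truth.target_probs()
    x_grid = scenario.x_scores
    mu_y_true = float(x_grid @ s_true)

    # the population equating function; the identity never is it
    rt = DiscreteScoreDistribution(x_grid, r_true, n=scenario.n)
    st = DiscreteScoreDistribution(x_grid, s_true, n=scenario.n)
    phi_true = equate(rt, st, bw.select_penalty(rt).h, bw.select_penalty(st).h)
    if not np.max(np.abs(phi_true.equated - x_grid)) > 0:
        raise RuntimeError("degenerate scenario: identity is the true equating")

    h_x = {m: [] for m in methods}
    h_y = {m: [] for m in equate_methods}
    mu_hat = {m: [] for m in equate_methods}
    curves = {m: [] for m in equate_methods}
    failures = 0
    rep_seeds = rep_root.spawn(scenario.G)
    for g, rs in enumerate(rep_seeds):
        try:
            child = rs.spawn(3)
            x_sample, y_sample = sample_replicate(truth, child[0])
            r, s, *_ = _presmooth_replicate(truth, x_sample, y_sample)
            run_licv = (licv_replicates is None or g < licv_replicates)
            for m in methods:
                if m == "licv":
                    if not run_licv:
                        continue
                    sel = bw.select_licv(r, n_repeats=licv_repeats,
                                         seed=child[1],
                                         presmooth_degree=licv_presmooth)
                else:
                    sel = bw.select_bandwidth(r, m)
                h_x[m].append(sel.h)
                if m in equate_methods:
                    if m == "licv":
                        sel_y = bw.select_licv(s, n_repeats=licv_repeats,
                                               seed=child[2],
                                               presmooth_degree=licv_presmooth)
                    else:
                        sel_y = bw.select_bandwidth(s, m)
                    h_y[m].append(sel_y.h)
                    res = equate(r, s, sel.h, sel_y.h, method=m)
                    mu_hat[m].append(float(res.equated @ r_true))
                    curves[m].append(res.equated)
        except (FittingError, ValueError) as exc:
            failures += 1
            if failures > max(2, scenario.G // 100):
                raise RuntimeError(
                    f"too many replicate failures ({failures}); last: {exc}")

    summary = SimulationSummary(scenario=scenario, methods=methods,
                                mu_y_true=mu_y_true,
                                true_equating=phi_true.equated,
                                n_failures=failures)
    for m in methods:
        hx = np.asarray(h_x[m])
        if hx.size == 0:
            continue
        summary.mean_h_x[m] = float(hx.mean())
        summary.var_h_x[m] = float(hx.var(ddof=1)) if hx.size > 1 else 0.0
        summary.h_x_samples[m] = hx
    for m in equate_methods:
        hy = np.asarray(h_y[m])
        if hy.size == 0:
            continue
        summary.mean_h_y[m] = float(hy.mean())
        summary.var_h_y[m] = float(hy.var(ddof=1)) if hy.size > 1 else 0.0
        mus = np.asarray(mu_hat[m])
        summary.replicate_means[m] = mus
        summary.mse[m] = mse_of_mean(mus, mu_y_true)
        cm = np.asarray(curves[m])
        summary.se_curves[m] = se_per_score(cm)
        summary.mean_curves[m] = cm.mean(axis=0)
        mean_result = EquatingResult(x_scores=x_grid, equated=cm.mean(axis=0),
                                     h_x=float("nan"), h_y=float("nan"),
                                     method=m)
        summary.pre[m] = pre_moments(mean_result, r_true, x_grid, s_true,
                                     p_max=10)
    return summary
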