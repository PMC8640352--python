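"""Bandwidth selectors: criterion oracles, closed forms, reductions."""

import numpy as np
import pytest

from keq import (ContinuizedDistribution, DiscreteScoreDistribution,
                 kernel_pdf_derivative, penalty_term, select_bandwidth,
                 select_ds, select_lcv, select_licv, select_penalty,
                 select_plcv, select_srt)
from keq.bandwidth import _ds_criterion, _lcv_criterion, _pen_criterion

RANGE = (0.05, 3.0)  # restricted search range for exhaustive-grid oracles


def exhaustive_min(criterion, lo=0.05, hi=3.0, step=0.001):
    hs = np.arange(lo, hi + step / 2, step)
    vals = criterion(hs)
    i = int(np.argmin(vals))
    return hs[i], vals[i]


@pytest.fixture
def jagged():
    """Alternating high/low probabilities (wiggly density at small h)."""
    probs = np.tile([0.3, 0.05], 3)
    probs = probs / probs.sum()
    return DiscreteScoreDistribution(np.arange(6), probs, n=200,
                                     counts=probs * 200)


class TestPenaltyTerm:
    def test_unimodal_large_h_few_flips(self, toy5):
        assert penalty_term(toy5, 5.0, flip="both") <= 1
        assert penalty_term(toy5, 5.0, flip="dip") == 0

    def test_jagged_small_h_flips(self, jagged):
        # tiny h: every occupied score point carries its own mode
        assert penalty_term(jagged, 0.05, flip="both") >= 1
        # moderate h: the low-probability points sit in valleys (U-shapes)
        assert penalty_term(jagged, 0.3, flip="dip") >= 1

    def test_central_flip_matches_derivative_signs(self, toy3):
        """A_j at the middle score agrees with the closed-form derivative."""
        cd = ContinuizedDistribution(toy3, 1.0)
        left = kernel_pdf_derivative(cd, 1.0 - 0.25)
        right = kernel_pdf_derivative(cd, 1.0 + 0.25)
        expected = int((left > 0 and right < 0) or (left < 0 and right > 0))
        counts_all = penalty_term(toy3, 1.0, flip="both")
        # symmetric 3-point: flips can only occur at the central score
        assert counts_all == expected

    def test_invalid_args(self, toy3):
        with pytest.raises(ValueError):
            penalty_term(toy3, -1.0)
        with pytest.raises(ValueError):
            penalty_term(toy3, 1.0, w=0.0)


class TestPenaltySelector:
    def test_kappa_zero_reduces_to_squared_term(self, random_dist):
        sel = select_penalty(random_dist, kappa=0.0, h_range=RANGE)
        h_star, _ = exhaustive_min(
            lambda hs: _pen_criterion(random_dist, 0.0, 0.25, hs))
        assert abs(sel.h - h_star) <= 0.001 + 1e-12

    def test_grid_oracle(self, random_dist):
        sel = select_penalty(random_dist, h_range=RANGE)
        h_star, _ = exhaustive_min(
            lambda hs: _pen_criterion(random_dist, 1.0, 0.25, hs))
        assert abs(sel.h - h_star) <= 0.001 + 1e-12


class TestSRT:
    def test_closed_form_value(self):
        d = DiscreteScoreDistribution(np.array([0, 1]), [0.5, 0.5], n=1000)
        # rescale to sigma = 12.78 via a two-point spread
        scores = np.array([0.0, 2 * 12.78])
        d = DiscreteScoreDistribution(scores, [0.5, 0.5], n=1000)
        h = select_srt(d).h
        assert h == pytest.approx(9 * 12.78 / np.sqrt(100 * 1000**0.4 - 81),
                                  abs=1e-10)
        assert h == pytest.approx(2.97, abs=0.01)

    def test_decreasing_in_n(self, toy5):
        hs = []
        for n in (10, 100, 1000, 100000):
            d = DiscreteScoreDistribution(toy5.scores, toy5.probs, n=n)
            hs.append(select_srt(d).h)
        assert all(a > b for a, b in zip(hs, hs[1:]))
        assert hs[-1] < 0.2

    def test_effective_scale_identity(self, toy5):
        """a(h) * h equals Silverman's 0.9 sigma n^{-1/5} by construction."""
        from keq import shrinkage_factor
        h = select_srt(toy5).h
        a = shrinkage_factor(toy5.var, h)
        assert a * h == pytest.approx(0.9 * toy5.sd * toy5.n**-0.2, abs=1e-10)

    def test_requires_n(self, toy3):
        with pytest.raises(ValueError):
            select_srt(toy3)


class TestDS:
    def test_star_grid_construction(self, toy5):
        # the criterion grid interleaves scores and midpoints: 2J-1 points
        x = toy5.scores
        star = np.empty(2 * x.size - 1)
        star[0::2] = x
        star[1::2] = (x[:-1] + x[1:]) / 2
        assert star.size == 2 * x.size - 1
        assert np.allclose(np.diff(star), 0.5)

    def test_grid_oracle(self, random_dist):
        q = 3.0
        sel = select_ds(random_dist, q=q, h_range=RANGE)
        h_star, _ = exhaustive_min(lambda hs: _ds_criterion(random_dist, q, hs))
        assert abs(sel.h - h_star) <= 0.001 + 1e-12

    def test_default_pilot_is_large(self, random_dist):
        sel = select_ds(random_dist)
        assert sel.diagnostics["pilot"] == pytest.approx(
            3.0 * select_srt(random_dist).h)


class TestLCV:
    def test_nonnegative(self, random_dist):
        hs = np.linspace(0.1, 5, 40)
        assert np.all(_lcv_criterion(random_dist, hs) >= 0)

    def test_three_point_hand_evaluation(self, toy3):
        """LCV at h=1 equals the explicit three-term leave-one-out sum."""
        from keq import shrinkage_factor
        a = shrinkage_factor(toy3.var, 1.0)
        mu = toy3.mean
        total = 0.0
        for j, xj in enumerate(toy3.scores):
            f_loo = sum(
                toy3.probs[l] * np.exp(-0.5 * ((xj - a * xl - (1 - a) * mu)
                                               / (a * 1.0))**2)
                / (np.sqrt(2 * np.pi) * a * 1.0)
                for l, xl in enumerate(toy3.scores) if l != j)
            total += (toy3.probs[j] - f_loo) ** 2
        assert _lcv_criterion(toy3, [1.0])[0] == pytest.approx(total / 3,
                                                               abs=1e-14)

    def test_grid_oracle(self, random_dist):
        sel = select_lcv(random_dist, h_range=RANGE)
        h_star, _ = exhaustive_min(lambda hs: _lcv_criterion(random_dist, hs))
        assert abs(sel.h - h_star) <= 0.001 + 1e-12

    def test_needs_two_points(self):
        d = DiscreteScoreDistribution(np.array([0.0, 1.0]), [0.4, 0.6])
        select_lcv(d, h_range=(0.1, 1.0))  # fine
        # J=1 fails already at the distribution level when continuizing
        with pytest.raises(ValueError):
            select_lcv(DiscreteScoreDistribution(np.array([1.0]), [1.0]),
                       h_range=(0.1, 1.0))


class TestPLCV:
    def test_kappa_zero_reduces_to_lcv(self, random_dist):
        a = select_plcv(random_dist, kappa=0.0, h_range=RANGE)
        b = select_lcv(random_dist, h_range=RANGE)
        assert a.h == pytest.approx(b.h, abs=1e-12)

    def test_penalty_never_decreases_h(self, jagged):
        """If the penalty is active at LCV's minimizer, PLCV moves h up."""
        lcv = select_lcv(jagged, h_range=RANGE)
        plcv = select_plcv(jagged, kappa=1.0, h_range=RANGE)
        if penalty_term(jagged, lcv.h) > 0:
            assert plcv.h >= lcv.h


class TestLiCV:
    def test_within_grid_bounds(self, random_dist):
        sel = select_licv(random_dist, n_repeats=5, seed=0)
        assert 0.01 <= sel.h <= 5.0

    def test_deterministic_split_grid_oracle(self):
        """With a forced balanced split, the argmax matches a direct
        evaluation of the Poisson log-likelihood over the grid."""
        # counts (2, 0, 2): every non-degenerate half-split is one test taker
        # at each occupied score, so the training density is fixed
        d = DiscreteScoreDistribution.from_counts(np.arange(3.0),
                                                  [2.0, 0.0, 2.0])
        grid = np.arange(0.1, 2.05, 0.1)
        sel = select_licv(d, grid=grid, n_repeats=3, seed=11)
        x = d.scores
        r1 = np.array([0.5, 0.0, 0.5])
        mu1, s21 = 1.0, 1.0
        best, best_ll = None, -np.inf
        for h in grid:
            a = np.sqrt(s21 / (s21 + h * h))
            ll = 0.0
            for j, n2 in enumerate([1.0, 0.0, 1.0]):
                f = sum(r1[l] * np.exp(-0.5 * ((x[j] - a * x[l] - (1 - a) * mu1)
                                               / (a * h))**2)
                        / (np.sqrt(2 * np.pi) * a * h) for l in range(3))
                lam = 2 * f
                ll += n2 * np.log(lam) - lam
            if ll > best_ll:
                best, best_ll = h, ll
        assert sel.h == pytest.approx(best, abs=1e-12)

    def test_reproducible_with_seed(self, random_dist):
        a = select_licv(random_dist, n_repeats=4, seed=5)
        b = select_licv(random_dist, n_repeats=4, seed=5)
        assert a.h == b.h

    def test_needs_counts(self, toy3):
        with pytest.raises(ValueError):
            select_licv(toy3)


class TestDispatch:
    def test_unknown_method(self, toy5):
        with pytest.raises(ValueError):
            select_bandwidth(toy5, "nope")

    @pytest.mark.parametrize("method", ["penalty", "ds", "lcv", "plcv"])
    def test_selected_h_in_range(self, random_dist, method):
        sel = select_bandwidth(random_dist, method, h_range=RANGE)
        assert RANGE[0] <= sel.h <= RANGE[1]
        assert np.isfinite(sel.criterion_value)
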