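"""Evaluation statistics: PRE, MSE, SE, analytical/bootstrap SEE, DTM."""

import numpy as np
import pytest

from keq import (ContinuizedDistribution, DiscreteScoreDistribution,
                 EquatingResult, dtm_compare, equate, mse_of_mean, pre_moments,
                 se_per_score, see_analytical, see_analytical_eg,
                 see_analytical_neat, see_bootstrap)
from keq.evaluation import _cdf_jacobian, _pse_jacobian
from keq.presmoothing import fit_loglinear_bivariate, fit_loglinear_univariate


def make_result(scores, equated):
    return EquatingResult(x_scores=np.asarray(scores, float),
                          equated=np.asarray(equated, float),
                          h_x=1.0, h_y=1.0)


class TestPRE:
    def test_identity_is_zero(self, toy5):
        res = make_result(toy5.scores, toy5.scores)
        pre = pre_moments(res, toy5.probs, toy5.scores, toy5.probs, p_max=10)
        assert np.allclose(pre, 0.0, atol=1e-12)

    def test_one_percent_mean_shift(self):
        y = np.array([1.0, 2.0, 3.0])
        s = np.array([0.2, 0.5, 0.3])
        mu = y @ s
        res = make_result(y, y * 1.01 * mu / mu)  # equated scaled by 1.01
        # equated moments computed against r = s on the same grid
        pre = pre_moments(res, s, y, s, p_max=1)
        assert pre[0] == pytest.approx(1.0, abs=1e-10)

    def test_hand_computed_first_two_moments(self):
        y = np.array([0.0, 1.0, 2.0])
        s = np.array([0.25, 0.5, 0.25])
        r = np.array([0.3, 0.4, 0.3])
        eq = np.array([0.2, 1.1, 1.9])
        # mu_1(Y) = 1.0, mu_2(Y) = 1.5
        # mu_1(eq) = .3*.2 + .4*1.1 + .3*1.9 = 1.07
        # mu_2(eq) = .3*.04 + .4*1.21 + .3*3.61 = 1.579
        pre = pre_moments(make_result(y, eq), r, y, s, p_max=2)
        assert pre[0] == pytest.approx(100 * (1.07 - 1.0) / 1.0, abs=1e-10)
        assert pre[1] == pytest.approx(100 * (1.579 - 1.5) / 1.5, abs=1e-10)

    def test_zero_moment_raises(self):
        y = np.array([-1.0, 1.0])
        s = np.array([0.5, 0.5])
        with pytest.raises(ZeroDivisionError):
            pre_moments(make_result(y, y), s, y, s, p_max=1)


class TestMSE:
    def test_no_error(self):
        assert mse_of_mean([2.0, 2.0, 2.0], 2.0) == 0.0

    def test_pure_variance(self):
        assert mse_of_mean([1.0, 2.0, 3.0], 2.0) == pytest.approx(1.0)

    def test_pure_bias(self):
        assert mse_of_mean([3.0, 3.0, 3.0], 2.0) == pytest.approx(1.0)

    def test_needs_two(self):
        with pytest.raises(ValueError):
            mse_of_mean([1.0], 1.0)

    def test_decomposition_identity(self):
        rng = np.random.default_rng(3)
        m = rng.normal(5.0, 2.0, size=40)
        mse = mse_of_mean(m, 4.0)
        assert mse == pytest.approx((m.mean() - 4.0) ** 2 + m.var(ddof=1),
                                    abs=1e-12)


class TestSE:
    def test_identical_curves(self):
        curves = np.tile(np.arange(5.0), (4, 1))
        assert np.allclose(se_per_score(curves), 0.0)

    def test_two_curves_hand_value(self):
        a = np.zeros(4)
        b = np.zeros(4)
        b[2] = 2.0
        se = se_per_score([a, b])
        assert se[2] == pytest.approx(np.sqrt(2.0))
        assert np.allclose(np.delete(se, 2), 0.0)

    def test_two_pass_oracle(self):
        rng = np.random.default_rng(9)
        curves = rng.normal(size=(30, 6))
        se = se_per_score(curves)
        for j in range(6):
            col = curves[:, j]
            mean = sum(col) / len(col)
            var = sum((c - mean) ** 2 for c in col) / (len(col) - 1)
            assert se[j] == pytest.approx(np.sqrt(var), abs=1e-12)


class TestDTM:
    def test_identical(self):
        assert not dtm_compare(np.arange(4.0), np.arange(4.0)).any()

    def test_single_flag(self):
        a = np.zeros(5)
        b = np.zeros(5)
        b[1] = 0.6
        flags = dtm_compare(a, b)
        assert flags.sum() == 1 and flags[1]

    def test_boundary_is_strict(self):
        a = np.zeros(3)
        b = np.full(3, 0.5)
        assert not dtm_compare(a, b).any()


class TestCdfJacobian:
    def test_matches_finite_differences(self, toy5):
        """Analytic dF/dr (including a and mu dependence) vs FD."""
        h = 0.9
        x_eval = np.array([0.7, 2.0, 3.4])
        cd = ContinuizedDistribution(toy5, h)
        jac = _cdf_jacobian(cd, x_eval)
        eps = 1e-6
        for m in range(toy5.probs.size):
            probs_p = toy5.probs.copy()
            probs_m = toy5.probs.copy()
            probs_p[m] += eps
            probs_m[m] -= eps
            # do not renormalize: the derivative is with respect to r_m alone
            fd_vals = []
            for probs in (probs_p, probs_m):
                mu = toy5.scores @ probs
                s2 = (toy5.scores**2) @ probs - mu**2
                a = np.sqrt(s2 / (s2 + h * h))
                z = (x_eval[:, None] - a * toy5.scores - (1 - a) * mu) / (a * h)
                from scipy.stats import norm
                fd_vals.append(norm.cdf(z) @ probs)
            fd = (fd_vals[0] - fd_vals[1]) / (2 * eps)
            assert np.allclose(jac[:, m], fd, atol=1e-5)


class TestPseJacobian:
    def test_matches_finite_differences(self, biv_table):
        w = 0.5
        p = biv_table.probs
        q = np.roll(biv_table.probs, 1, axis=0)  # a different joint table
        dr_dp, dr_dq, ds_dp, ds_dq = _pse_jacobian(p, q, w)

        eps = 1e-7
        rng = np.random.default_rng(0)
        for _ in range(4):
            j = rng.integers(p.shape[0])
            l = rng.integers(p.shape[1])
            pp = p.copy()
            pm = p.copy()
            pp[j, l] += eps
            pm[j, l] -= eps
            # finite difference without renormalizing (partial derivative)
            def r_raw(pf):
                pa = pf.sum(axis=0)
                qa = q.sum(axis=0)
                t = w * pa + (1 - w) * qa
                return (pf / pa) @ t, (q / qa) @ t
            r_p, s_p = r_raw(pp)
            r_m, s_m = r_raw(pm)
            idx = j * p.shape[1] + l
            assert np.allclose(dr_dp[:, idx], (r_p - r_m) / (2 * eps),
                               atol=1e-6)
            assert np.allclose(ds_dp[:, idx], (s_p - s_m) / (2 * eps),
                               atol=1e-6)


class TestAnalyticalSEE:
    def _eg_setup(self, n=800, seed=5):
        rng = np.random.default_rng(seed)
        x = np.arange(15.0)
        law = np.exp(1.2 * x - 0.09 * x**2)
        probs = law / law.sum()
        cx = rng.multinomial(n, probs).astype(float)
        cy = rng.multinomial(n, probs).astype(float)
        dx = DiscreteScoreDistribution.from_counts(x, cx)
        dy = DiscreteScoreDistribution.from_counts(x, cy)
        return dx, dy

    def test_nonnegative(self):
        dx, dy = self._eg_setup()
        res = see_analytical_eg(dx, dy, 0.7, 0.7)
        assert np.all(res.see >= 0)

    def test_root_n_scaling(self):
        """Doubling both sample sizes divides the SEE by about sqrt(2)."""
        dx, dy = self._eg_setup(n=1000)
        dx2 = DiscreteScoreDistribution(dx.scores, dx.probs, counts=dx.counts,
                                        n=2000)
        dy2 = DiscreteScoreDistribution(dy.scores, dy.probs, counts=dy.counts,
                                        n=2000)
        see1 = see_analytical_eg(dx, dy, 0.7, 0.7).see
        see2 = see_analytical_eg(dx2, dy2, 0.7, 0.7).see
        mid = slice(4, 11)
        ratio = see1[mid] / see2[mid]
        assert np.allclose(ratio, np.sqrt(2.0), rtol=0.05)

    def test_saturated_presmoothing_equals_multinomial(self):
        """A saturated log-linear fit reproduces the no-presmoothing SEE."""
        x = np.arange(6.0)
        cx = np.array([12.0, 40.0, 90.0, 80.0, 50.0, 28.0])
        cy = np.array([20.0, 55.0, 85.0, 70.0, 45.0, 25.0])
        dx = DiscreteScoreDistribution.from_counts(x, cx)
        dy = DiscreteScoreDistribution.from_counts(x, cy)
        fit_x = fit_loglinear_univariate(x, cx, 5)
        fit_y = fit_loglinear_univariate(x, cy, 5)
        see_fit = see_analytical_eg(fit_x, fit_y, 0.8, 0.8).see
        see_raw = see_analytical_eg(dx, dy, 0.8, 0.8).see
        assert np.allclose(see_fit, see_raw, rtol=1e-4, atol=1e-8)

    def test_neat_see_runs_and_is_positive(self, biv_table):
        fit_p = fit_loglinear_bivariate(biv_table, 2, 2, ((1, 1),))
        fit_q = fit_loglinear_bivariate(biv_table, 2, 2, ((1, 1),))
        res = see_analytical_neat(fit_p, fit_q, 0.5, 0.8, 0.8)
        assert res.see.shape == biv_table.x_scores.shape
        assert np.all(res.see >= 0)
        assert np.all(np.isfinite(res.see))


class TestBootstrapSEE:
    def test_degenerate_input_raises(self):
        d = DiscreteScoreDistribution(np.array([0.0, 1.0]), [1.0, 0.0],
                                      counts=[50.0, 0.0], n=50)
        with pytest.raises(ValueError):
            see_bootstrap(d, d, B=5, seed=0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(11)
        x = np.arange(8.0)
        probs = np.exp(-0.5 * (x - 3.5) ** 2 / 2)
        probs /= probs.sum()
        cx = rng.multinomial(300, probs).astype(float)
        cy = rng.multinomial(300, probs).astype(float)
        dx = DiscreteScoreDistribution.from_counts(x, cx)
        dy = DiscreteScoreDistribution.from_counts(x, cy)
        a = see_bootstrap(dx, dy, B=8, seed=42,
                          bandwidth_kwargs={"h_range": (0.1, 3.0)})
        b = see_bootstrap(dx, dy, B=8, seed=42,
                          bandwidth_kwargs={"h_range": (0.1, 3.0)})
        assert np.array_equal(a, b)
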