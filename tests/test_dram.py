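"""DRAM building blocks and chain-law checks on analytic targets."""

import math

import numpy as np
import pytest
from scipy import stats

from refuge_dynamics import (
    SamplerConfig,
    adapt_covariance,
    dr_acceptance,
    log_posterior_kernel,
    propose,
    run_dram,
    sample_error_variance,
)

WIDE = (np.array([-100.0, -100.0]), np.array([100.0, 100.0]))


class TestKernel:
    def test_flat_prior_inside_box(self):
        lo = np.zeros(2)
        hi = np.array([1.0, 3000.0])
        a = log_posterior_kernel([0.5, 1500.0], 10.0, 2.0, (lo, hi))
        b = log_posterior_kernel([0.9, 10.0], 10.0, 2.0, (lo, hi))
        assert a == b == pytest.approx(-10.0 / 4.0)

    @pytest.mark.parametrize("theta", [[0.5, 3500.0], [1.2, 100.0]])
    def test_out_of_bounds_is_minus_infinity(self, theta):
        # carrying capacity capped at 3000, removal fraction at 1
        lo = np.array([1e-6, 1.0])
        hi = np.array([1.0, 3000.0])
        assert log_posterior_kernel(theta, 1.0, 1.0, (lo, hi)) == -math.inf

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            log_posterior_kernel([0.0], 1.0, 0.0, (np.array([-1.0]),
                                                   np.array([1.0])))


class TestPropose:
    def test_zero_noise_returns_current(self):
        chol = np.linalg.cholesky(np.array([[2.0, 0.3], [0.3, 1.0]]))
        cur = np.array([1.0, 2.0])
        np.testing.assert_array_equal(
            propose(cur, chol, stage=1, dr_downscale=3.0, z=np.zeros(2)), cur)

    def test_stage_two_covariance_shrinks_by_downscale_squared(self, rng):
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        chol = np.linalg.cholesky(cov)
        draws1 = np.array([propose(np.zeros(2), chol, 1, 3.0, rng)
                           for _ in range(100_000)])
        draws2 = np.array([propose(np.zeros(2), chol, 2, 3.0, rng)
                           for _ in range(100_000)])
        np.testing.assert_allclose(np.cov(draws1.T), cov, atol=0.03)
        np.testing.assert_allclose(np.cov(draws2.T), cov / 9.0, atol=0.01)

    def test_fixed_seed_reproducible(self):
        chol = np.eye(3)
        a = propose(np.zeros(3), chol, 1, 3.0, np.random.default_rng(5))
        b = propose(np.zeros(3), chol, 1, 3.0, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestDrAcceptance:
    def test_uphill_first_stage_is_certain(self):
        chol = np.eye(1)
        p = dr_acceptance([np.zeros(1), np.ones(1)], [-5.0, -1.0], chol, 3.0)
        assert p == 1.0

    def test_downhill_first_stage_is_metropolis_ratio(self):
        chol = np.eye(1)
        p = dr_acceptance([np.zeros(1), np.ones(1)], [-1.0, -3.0], chol, 3.0)
        assert p == pytest.approx(math.exp(-2.0))

    def test_out_of_bounds_second_stage_rejected(self):
        chol = np.eye(1)
        pts = [np.zeros(1), np.ones(1), 2 * np.ones(1)]
        p = dr_acceptance(pts, [-1.0, -3.0, -math.inf], chol, 3.0)
        assert p == 0.0

    def test_second_stage_uphill_move_has_high_acceptance(self):
        chol = np.eye(1)
        pts = [np.zeros(1), np.ones(1), np.array([-0.5])]
        p = dr_acceptance(pts, [-1.0, -10.0, -0.5], chol, 3.0)
        assert 0.0 < p <= 1.0
        # a much better second candidate is near-surely accepted
        p_big = dr_acceptance(pts, [-5.0, -50.0, -0.01], chol, 3.0)
        assert p_big == pytest.approx(1.0)


class TestAdaptCovariance:
    def test_scaled_sample_covariance(self, rng):
        cov = np.array([[1.0, 0.4], [0.4, 2.0]])
        hist = rng.multivariate_normal(np.zeros(2), cov, size=200_000)
        adapted = adapt_covariance(hist, 2)
        np.testing.assert_allclose(adapted, (2.4**2 / 2) * cov, rtol=0.02)

    def test_degenerate_history_floors_at_jitter(self):
        hist = np.ones((50, 3))
        adapted = adapt_covariance(hist, 3)
        np.testing.assert_allclose(adapted, (2.4**2 / 3) * 1e-10 * np.eye(3))

    def test_result_is_symmetric_positive_definite(self, rng):
        hist = rng.normal(size=(500, 4))
        a = adapt_covariance(hist)
        np.testing.assert_allclose(a, a.T)
        assert np.all(np.linalg.eigvalsh(a) > 0)

    def test_too_short_history_rejected(self):
        with pytest.raises(ValueError):
            adapt_covariance(np.ones((1, 2)))


class TestErrorVariance:
    def test_posterior_concentrates_at_ss_over_n(self, rng):
        n, ss = 100_000, 250_000.0
        draws = [sample_error_variance(ss, n, 0.01, 0.01, rng)
                 for _ in range(2000)]
        assert np.mean(draws) == pytest.approx(ss / n, rel=0.01)

    def test_prior_only_matches_inverse_gamma_quantiles(self, rng):
        shape, scale = 3.0, 2.0
        draws = np.array([sample_error_variance(0.0, 0, shape, scale, rng)
                          for _ in range(20_000)])
        ref = stats.invgamma(shape, scale=scale)
        for q in (0.1, 0.5, 0.9):
            assert np.quantile(draws, q) == pytest.approx(ref.ppf(q), rel=0.05)

    def test_fixed_seed_reproducible(self):
        a = sample_error_variance(10.0, 5, 0.01, 0.01, np.random.default_rng(1))
        b = sample_error_variance(10.0, 5, 0.01, 0.01, np.random.default_rng(1))
        assert a == b


def _gaussian_problem(seed=7, n=40):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ np.array([1.0, -2.0]) + rng.normal(scale=0.5, size=n)
    bhat = np.linalg.solve(X.T @ X, X.T @ y)
    post_cov = 0.25 * np.linalg.inv(X.T @ X)
    return X, y, bhat, post_cov


class TestRunDram:
    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="burn_in"):
            SamplerConfig(n_samples=100, burn_in=100)
        with pytest.raises(ValueError, match="dr_stages|max_dr_stages"):
            SamplerConfig(max_dr_stages=4)

    def test_retained_samples_respect_bounds(self):
        ss = lambda b: float(b @ b)
        lo, hi = np.array([-0.5, -0.5]), np.array([0.5, 0.5])
        cfg = SamplerConfig(n_samples=3000, burn_in=500, seed=11,
                            sample_sigma2=False, sigma2=0.05)
        res = run_dram(ss, np.zeros(2), (lo, hi), 10, cfg)
        assert np.all(res.samples >= lo) and np.all(res.samples <= hi)

    def test_chain_is_bitwise_reproducible(self):
        X, y, bhat, _ = _gaussian_problem()
        ss = lambda b: float(((y - X @ b) ** 2).sum())
        cfg = SamplerConfig(n_samples=2000, burn_in=200, seed=42,
                            sample_sigma2=False, sigma2=0.25)
        a = run_dram(ss, bhat, WIDE, len(y), cfg)
        b = run_dram(ss, bhat, WIDE, len(y), cfg)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_evaluation_budget_bounded_by_stages(self):
        X, y, bhat, _ = _gaussian_problem()
        ss = lambda b: float(((y - X @ b) ** 2).sum())
        cfg = SamplerConfig(n_samples=2000, burn_in=200, seed=0,
                            sample_sigma2=False, sigma2=0.25)
        res = run_dram(ss, bhat, WIDE, len(y), cfg)
        assert res.n_evaluations <= 2000 * cfg.max_dr_stages + 1

    def test_plain_metropolis_matches_textbook_reference(self):
        """With one DR stage and adaptation disabled the sampler is plain
        Metropolis; an independent textbook loop fed the same RNG stream
        makes identical accept/reject decisions."""
        X, y, bhat, _ = _gaussian_problem()
        ss = lambda b: float(((y - X @ b) ** 2).sum())
        n_samp = 3000
        cfg = SamplerConfig(n_samples=n_samp, burn_in=0, max_dr_stages=1,
                            adapt_interval=n_samp + 1, seed=9,
                            sample_sigma2=False, sigma2=0.25)
        res = run_dram(ss, bhat, WIDE, len(y), cfg)

        rng = np.random.default_rng(9)
        scale = np.maximum(0.05 * np.abs(bhat), 1e-4 * (WIDE[1] - WIDE[0]))
        chol = np.diag(scale)
        x = bhat.copy()
        lp = lambda b: -ss(b) / (2 * 0.25)
        ref = np.empty((n_samp, 2))
        for i in range(n_samp):
            z = rng.standard_normal(2)
            yprop = x + chol @ z
            if math.log(rng.uniform()) < lp(yprop) - lp(x):
                x = yprop
            ref[i] = x
        np.testing.assert_array_equal(res.samples, ref)

    def test_gaussian_target_quantiles_match_theory(self):
        """Marginal 2.5/50/97.5% quantiles on a known Gaussian posterior
        agree with theory within Monte-Carlo error."""
        X, y, bhat, post_cov = _gaussian_problem()
        ss = lambda b: float(((y - X @ b) ** 2).sum())
        cfg = SamplerConfig(n_samples=30_000, burn_in=3_000, seed=15,
                            sample_sigma2=False, sigma2=0.25)
        res = run_dram(ss, bhat, WIDE, len(y), cfg)
        sd = np.sqrt(np.diag(post_cov))
        for j in range(2):
            for q, zq in ((0.025, -1.96), (0.5, 0.0), (0.975, 1.96)):
                got = np.quantile(res.samples[:, j], q)
                assert got == pytest.approx(bhat[j] + zq * sd[j],
                                            abs=0.15 * sd[j])
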