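"""Distribution core: density, CDF, quantile, sampling, likelihood, score."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from ngri.bccg import (
    BCCGParams,
    bccg_cdf,
    bccg_loglik,
    bccg_pdf,
    bccg_quantile,
    bccg_rvs,
    bccg_score,
    bccg_z,
)

P_GRID = [0.025, 0.25, 0.5, 0.75, 0.975]


class TestParams:
    @pytest.mark.parametrize("mu,sigma,nu", [(-1, 0.1, 1), (0, 0.1, 1), (1, 0, 1),
                                             (1, -0.5, 1), (np.inf, 0.1, 1), (1, 0.1, np.nan)])
    def test_invalid_rejected(self, mu, sigma, nu):
        with pytest.raises(ValueError):
            BCCGParams(mu, sigma, nu)


class TestZ:
    @pytest.mark.parametrize("nu", [-1.0, -0.3, 0.0, 0.8, 2.0])
    def test_median_maps_to_zero(self, nu):
        assert bccg_z(4.50, BCCGParams(4.50, 0.06, nu)) == pytest.approx(0.0, abs=1e-12)

    def test_log_branch_closed_form(self):
        # y = 2 mu, sigma = 0.5, nu = 0 -> ln(2)/0.5
        assert bccg_z(2.0, BCCGParams(1.0, 0.5, 0.0)) == pytest.approx(np.log(2) / 0.5, rel=1e-12)

    def test_continuity_in_nu_at_zero(self):
        p0 = BCCGParams(4.5, 0.09, 0.0)
        z0 = bccg_z(5.0, p0)
        for eps in (1e-6, -1e-6):
            assert bccg_z(5.0, BCCGParams(4.5, 0.09, eps)) == pytest.approx(z0, abs=1e-5)

    def test_power_branch_matches_direct_formula(self):
        y, mu, sigma, nu = 5.0, 4.5, 0.09, 0.5
        direct = ((y / mu) ** nu - 1) / (nu * sigma)
        assert bccg_z(y, BCCGParams(mu, sigma, nu)) == pytest.approx(direct, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bccg_z(0.0, BCCGParams(1, 0.1, 1))


class TestPdfCdf:
    @pytest.mark.parametrize("sigma", [0.03, 0.1, 0.3])
    @pytest.mark.parametrize("nu", [-1.0, -0.5, 0.0, 0.5, 1.0, 2.0])
    def test_exact_pdf_integrates_to_one(self, sigma, nu):
        p = BCCGParams(4.5, sigma, nu)
        f = lambda y: bccg_pdf(y, p, "exact")
        # split at the bulk so quadrature resolves both the peak and the tail
        bulk, _ = quad(f, 1e-12, 50.0, points=[4.5], limit=300)
        tail, _ = quad(f, 50.0, np.inf, limit=300)
        assert bulk + tail == pytest.approx(1.0, abs=1e-8)

    def test_lognormal_closed_form(self):
        # nu = 0, mu = 1, sigma = 0.5, y = 1 -> phi(0)/0.5
        expect = stats.norm.pdf(0) / 0.5
        assert bccg_pdf(1.0, BCCGParams(1, 0.5, 0.0)) == pytest.approx(expect, rel=1e-12)

    def test_lms_equals_exact_when_truncation_negligible(self):
        p = BCCGParams(4.5, 0.06, 0.8)  # sigma*|nu| = 0.048
        y = np.linspace(3.0, 6.5, 200)
        lms = bccg_pdf(y, p, "lms")
        exact = bccg_pdf(y, p, "exact")
        assert np.max(np.abs(lms / exact - 1)) < 1e-10

    def test_cdf_median_is_half_lms(self):
        assert bccg_cdf(4.5, BCCGParams(4.5, 0.2, -0.7), "lms") == pytest.approx(0.5)

    def test_cdf_matches_pdf_quadrature(self):
        p = BCCGParams(4.5, 0.2, -0.5)
        for y in [3.0, 4.5, 6.0]:
            num, _ = quad(lambda t: bccg_pdf(t, p, "exact"), 1e-12, y, limit=300)
            assert bccg_cdf(y, p, "exact") == pytest.approx(num, abs=1e-8)

    def test_lognormal_upper_tail(self):
        y = float(np.exp(0.5 * stats.norm.ppf(0.975)))
        assert bccg_cdf(y, BCCGParams(1, 0.5, 0.0)) == pytest.approx(0.975, abs=1e-4)

    def test_cdf_monotone(self):
        p = BCCGParams(4.5, 0.25, 1.5)
        y = np.linspace(0.5, 12, 400)
        for mode in ("lms", "exact"):
            assert np.all(np.diff(bccg_cdf(y, p, mode)) >= 0)

    def test_modes_agree_for_small_sigma_nu(self):
        # Phi(1/(sigma|nu|)) >= 1 - 3e-7 whenever sigma|nu| <= 0.2
        p = BCCGParams(4.5, 0.2, 1.0)
        y = np.linspace(2.0, 8.0, 100)
        assert np.max(np.abs(bccg_cdf(y, p, "lms") - bccg_cdf(y, p, "exact"))) < 1e-6


class TestQuantile:
    @pytest.mark.parametrize("sigma,nu", [(0.06, 0.8), (0.3, -1.2), (0.1, 0.0)])
    def test_median_is_mu(self, sigma, nu):
        assert bccg_quantile(0.5, BCCGParams(4.5, sigma, nu), "lms") == pytest.approx(4.5)

    @pytest.mark.parametrize("mode", ["lms", "exact"])
    def test_cdf_quantile_round_trip(self, mode):
        p = BCCGParams(4.5, 0.2, -0.7)
        for prob in P_GRID:
            y = bccg_quantile(prob, p, mode)
            assert bccg_cdf(y, p, mode) == pytest.approx(prob, abs=1e-10)

    def test_lognormal_closed_form(self):
        assert bccg_quantile(0.975, BCCGParams(1, 0.5, 0.0)) == pytest.approx(
            np.exp(0.5 * stats.norm.ppf(0.975)), rel=1e-9)

    def test_strictly_increasing_in_p(self):
        p = BCCGParams(4.5, 0.1, 1.3)
        q = bccg_quantile(np.linspace(0.01, 0.99, 99), p)
        assert np.all(np.diff(q) > 0)

    def test_gaussian_limit(self):
        # nu = 1, sigma -> 0: quantiles converge to Normal(mu, (mu sigma)^2)
        mu, sigma = 4.5, 1e-3
        p = BCCGParams(mu, sigma, 1.0)
        for prob in P_GRID:
            expect = mu + mu * sigma * stats.norm.ppf(prob)
            assert bccg_quantile(prob, p) == pytest.approx(expect, rel=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bccg_quantile(0.0, BCCGParams(1, 0.1, 1))
        with pytest.raises(ValueError):
            bccg_quantile(1.0, BCCGParams(1, 0.1, 1))
        with pytest.raises(ValueError, match="nu"):
            # 1 + nu*sigma*z <= 0 for this extreme tail
            bccg_quantile(1e-12, BCCGParams(1, 0.5, 2.0), "lms")


class TestSampling:
    def test_empty_and_deterministic(self):
        p = BCCGParams(4.5, 0.06, 0.8)
        assert bccg_rvs(0, p).size == 0
        a = bccg_rvs(500, p, seed=42)
        b = bccg_rvs(500, p, seed=42)
        np.testing.assert_array_equal(a, b)
        assert np.all(a > 0)

    def test_empirical_percentile_matches_quantile(self):
        p = BCCGParams(4.5, 0.06, 0.8)
        n = 200_000
        x = bccg_rvs(n, p, seed=3)
        emp = np.quantile(x, 0.975, method="linear")
        target = bccg_quantile(0.975, p)
        # MC standard error of the empirical 97.5th percentile
        dens = bccg_pdf(target, p)
        se = np.sqrt(0.975 * 0.025 / n) / dens
        assert abs(emp - target) < 3 * se


class TestLoglik:
    def test_single_observation(self):
        p = BCCGParams(4.5, 0.06, 0.8)
        ll = bccg_loglik([5.0], [4.5], [0.06], 0.8)
        assert ll == pytest.approx(np.log(bccg_pdf(5.0, p)), rel=1e-12)

    def test_matches_lognormal_at_nu_zero(self):
        rng = np.random.default_rng(0)
        y = rng.lognormal(1.0, 0.4, size=200)
        ll = bccg_loglik(y, np.e, 0.4, 0.0)
        expect = stats.lognorm.logpdf(y, s=0.4, scale=np.e).sum()
        assert ll == pytest.approx(expect, rel=1e-10)

    def test_maximized_near_truth(self):
        y = bccg_rvs(5000, BCCGParams(4.5, 0.06, 0.8), seed=5)
        mus = np.linspace(4.0, 5.0, 41)
        lls = [bccg_loglik(y, m, 0.06, 0.8) for m in mus]
        assert abs(mus[int(np.argmax(lls))] - 4.5) <= 0.05

    def test_error_names_offending_index(self):
        with pytest.raises(ValueError, match="index 2"):
            bccg_loglik([1.0, 2.0, -3.0], 1.0, 0.1, 0.5)


class TestScore:
    @pytest.mark.parametrize("mode", ["lms", "exact"])
    def test_matches_finite_differences(self, mode):
        rng = np.random.default_rng(11)
        h = 1e-6
        for _ in range(20):
            mu = rng.uniform(1.0, 8.0)
            sigma = rng.uniform(0.03, 0.4)
            nu = rng.uniform(-2.0, 2.0)
            y = mu * rng.uniform(0.7, 1.4)
            s = bccg_score(y, BCCGParams(mu, sigma, nu), mode)

            def ll(m, sg, v):
                return bccg_loglik([y], m, sg, v, mode)

            fd = (
                (ll(mu + h, sigma, nu) - ll(mu - h, sigma, nu)) / (2 * h),
                (ll(mu, sigma + h, nu) - ll(mu, sigma - h, nu)) / (2 * h),
                (ll(mu, sigma, nu + h) - ll(mu, sigma, nu - h)) / (2 * h),
            )
            for a, b in zip(s, fd):
                assert a == pytest.approx(b, rel=1e-5, abs=1e-6)

    def test_gaussian_limit_of_mu_score(self):
        # nu = 1, small sigma: dl/dmu ~ (y - mu)/(mu sigma)^2
        mu, sigma, y = 4.5, 1e-3, 4.503
        s = bccg_score(y, BCCGParams(mu, sigma, 1.0))
        assert s[0] == pytest.approx((y - mu) / (mu * sigma) ** 2, rel=1e-3)

    def test_score_at_median_small_nu_limit(self):
        # at y = mu the z term vanishes: dl/dmu = -nu/mu exactly (lms)
        for nu in (-0.7, 0.4, 1.5):
            s = bccg_score(4.5, BCCGParams(4.5, 0.06, nu), "lms")
            assert s[0] == pytest.approx(-nu / 4.5, rel=1e-10)
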