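"""One-locus posterior: closed forms against the quadrature oracle."""

import math

import numpy as np
import pytest

from spikewgr.onelocus import (
    EvidenceResult,
    HpdGridSpec,
    LocusSufficientStats,
    PriorSpec,
    bayes_factor,
    continuous_density,
    hpd_credibility,
    posterior_cdf,
    posterior_mean,
    posterior_mean_scalar,
    truncated_normal_mean,
)

from conftest import oracle_posterior


def make_post(Y, s2, gamma, lam):
    stats = LocusSufficientStats(xtx=1.0 / s2, xty=Y / s2, sigma_e2=1.0)
    return posterior_mean(stats, PriorSpec(gamma, lam))


class TestTruncatedNormalMean:
    def test_half_normal(self):
        assert truncated_normal_mean("upper", 0.0, 1.0) == pytest.approx(math.sqrt(2 / math.pi), abs=1e-12)
        assert truncated_normal_mean("lower", 0.0, 1.0) == pytest.approx(-math.sqrt(2 / math.pi), abs=1e-12)

    def test_deep_tail_against_quadrature(self):
        from scipy.integrate import quad

        mu, s2 = -8.0, 1.0
        num = quad(lambda g: g * math.exp(-((g - mu) ** 2) / 2 + (mu**2) / 2), 0, 30, limit=200)[0]
        den = quad(lambda g: math.exp(-((g - mu) ** 2) / 2 + (mu**2) / 2), 0, 30, limit=200)[0]
        got = truncated_normal_mean("upper", mu, s2)
        assert got > 0.0
        assert got == pytest.approx(num / den, rel=1e-10)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            truncated_normal_mean("upper", 0.0, -1.0)


class TestPosteriorMean:
    def test_symmetry_at_zero(self):
        assert make_post(0.0, 0.3, 0.01, 5.0).ghat == 0.0

    def test_flat_slab_limit(self):
        post = make_post(2.0, 0.1, 1.0, 1e-8)
        assert abs(post.ghat - 2.0) < 1e-6

    def test_against_quadrature(self):
        post = make_post(1.0, 0.25, 0.01, 10.0)
        oracle = oracle_posterior(1.0, 0.25, 0.01, 10.0)
        assert post.ghat == pytest.approx(oracle["mean"], rel=1e-8)

    def test_scalar_path_matches(self):
        for Y, s2, g, lam in [(0.7, 0.04, 0.005, 40.0), (-2.0, 0.5, 0.5, 1.0)]:
            assert posterior_mean_scalar(Y, s2, g, lam) == pytest.approx(make_post(Y, s2, g, lam).ghat, rel=1e-12)

    def test_no_overflow_for_extreme_signal(self):
        # |Y|/sigma = 40 and lam*sigma large must stay finite (log-space contract)
        with np.errstate(over="raise"):
            post = make_post(4.0, 0.01, 0.005, 1000.0)
        assert np.isfinite(post.ghat)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            LocusSufficientStats(xtx=-1.0, xty=0.0, sigma_e2=1.0)
        with pytest.raises(ValueError):
            LocusSufficientStats(xtx=1.0, xty=float("nan"), sigma_e2=1.0)
        with pytest.raises(ValueError):
            PriorSpec(0.0, 1.0)
        with pytest.raises(ValueError):
            PriorSpec(0.5, -1.0)


class TestPosteriorCdf:
    def test_normalization_limits(self):
        post = make_post(1.0, 0.25, 0.01, 10.0)
        sigma = math.sqrt(post.sigma2)
        assert posterior_cdf(-(abs(post.Y) + 40 * sigma), post) == pytest.approx(0.0, abs=1e-12)
        assert posterior_cdf(abs(post.Y) + 40 * sigma, post) == pytest.approx(1.0, abs=1e-10)

    def test_jump_height_is_spike_mass(self):
        for Y, s2, g, lam in [(1.0, 0.25, 0.01, 10.0), (-0.3, 0.02, 0.005, 50.0), (0.05, 0.01, 0.5, 2.0)]:
            post = make_post(Y, s2, g, lam)
            eps = 1e-12
            jump = posterior_cdf(eps, post) - posterior_cdf(-eps, post)
            expect = math.exp(post.log_laplace_const + post.log_T3 - post.log_py)
            assert jump == pytest.approx(expect, rel=1e-6)
            oracle = oracle_posterior(Y, s2, g, lam)
            assert jump == pytest.approx(oracle["spike_prob"], rel=1e-6)

    def test_value_against_quadrature(self):
        post = make_post(1.0, 0.25, 0.01, 10.0)
        oracle = oracle_posterior(1.0, 0.25, 0.01, 10.0)
        assert posterior_cdf(0.3, post) == pytest.approx(oracle["cdf"](0.3), abs=1e-8)

    def test_monotone_in_t(self):
        post = make_post(-0.8, 0.1, 0.02, 8.0)
        ts = np.linspace(-4, 4, 81)
        vals = [posterior_cdf(float(t), post) for t in ts]
        assert np.all(np.diff(vals) >= -1e-12)


class TestContinuousDensity:
    @pytest.mark.parametrize("params", [(1.0, 0.25, 0.01, 10.0), (-2.0, 0.04, 0.005, 100.0), (0.1, 1.0, 0.9, 0.5)])
    def test_continuous_at_zero(self, params):
        post = make_post(*params)
        left = continuous_density(-1e-300, post)
        right = continuous_density(1e-300, post)
        assert left == pytest.approx(right, rel=1e-12)
        assert left == pytest.approx(continuous_density(0.0, post), rel=1e-12)

    def test_nonnegative_and_mass_complement(self):
        from scipy.integrate import quad

        post = make_post(0.6, 0.09, 0.05, 4.0)
        grid = np.linspace(-5, 5, 201)
        dens = [continuous_density(float(g), post) for g in grid]
        assert min(dens) >= 0.0
        mass = quad(lambda g: continuous_density(g, post), -6, 0, limit=200)[0]
        mass += quad(lambda g: continuous_density(g, post), 0, 6, limit=200)[0]
        eps = 1e-12
        jump = posterior_cdf(eps, post) - posterior_cdf(-eps, post)
        assert mass == pytest.approx(1.0 - jump, abs=1e-8)


class TestHpdCredibility:
    def test_zero_estimate_convention(self):
        post = make_post(0.0, 0.25, 0.01, 10.0)
        ev = hpd_credibility(post, HpdGridSpec(-1.0, 1.0))
        assert ev == EvidenceResult(kappa=0.0, moe=1.0, t1=0.0, t2=0.0)

    def test_overwhelming_signal(self):
        # |Y| = 40 sigma: essentially certain nonzero effect
        post = make_post(4.0, 0.01, 0.5, 1.0)
        ev = hpd_credibility(post, HpdGridSpec(10 * -abs(post.ghat), 10 * abs(post.ghat)))
        assert ev.kappa > 0.9999
        assert ev.t1 == 0.0 and ev.t2 > 0.0

    def test_borders_and_kappa_against_oracle(self):
        # strong positive case where the HPD interval is nondegenerate
        Y, s2, gamma, lam = 1.0, 0.01, 0.05, 5.0
        post = make_post(Y, s2, gamma, lam)
        grid = HpdGridSpec(-10 * abs(post.ghat), 10 * abs(post.ghat), steps=2000)
        ev = hpd_credibility(post, grid)
        # border from root-bracketing the density equation f3(t) = f3(0+)
        from scipy.optimize import brentq

        mode = Y - lam * s2
        t_star = brentq(
            lambda g: continuous_density(g, post) - continuous_density(0.0, post), mode, mode + 10 * math.sqrt(s2)
        )
        step = (grid.m_upper - grid.m_lower) / grid.steps
        assert abs(ev.t2 - t_star) <= step + 1e-12
        oracle = oracle_posterior(Y, s2, gamma, lam)
        kappa_oracle = oracle["cdf"](t_star) - oracle["cdf"](1e-300)
        dens_max = continuous_density(mode, post)
        assert abs(ev.kappa - kappa_oracle) <= 2 * step * dens_max

    def test_exact_border_flag(self):
        Y, s2, gamma, lam = 1.0, 0.01, 0.05, 5.0
        post = make_post(Y, s2, gamma, lam)
        ev = hpd_credibility(post, HpdGridSpec(0.0, 0.0, exact=True))
        assert ev.t2 == pytest.approx(2 * (Y - lam * s2), rel=1e-12)

    def test_negative_mirror(self):
        post = make_post(-1.0, 0.01, 0.05, 5.0)
        ev = hpd_credibility(post, HpdGridSpec(-10 * abs(post.ghat), 10 * abs(post.ghat)))
        mirror = hpd_credibility(
            make_post(1.0, 0.01, 0.05, 5.0),
            HpdGridSpec(-10 * abs(post.ghat), 10 * abs(post.ghat)),
        )
        assert ev.kappa == pytest.approx(mirror.kappa, rel=1e-9)
        assert ev.t2 == 0.0 and ev.t1 == pytest.approx(-mirror.t2, abs=1e-12)

    def test_invalid_grid(self):
        post = make_post(1.0, 0.25, 0.01, 10.0)
        with pytest.raises(ValueError):
            hpd_credibility(post, HpdGridSpec(1.0, -1.0))


class TestBayesFactor:
    def test_null_estimate_gives_unit_factor(self):
        assert bayes_factor(0.0, 3.0, 10.0, 1.0) == 0.0  # log B = 0

    def test_rss_identity(self, rng):
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        ghat = 0.35
        s2 = 0.8
        log_b = bayes_factor(ghat, float(x @ y), float(x @ x), s2)
        rss0 = float(y @ y)
        rss1 = float((y - ghat * x) @ (y - ghat * x))
        assert log_b == pytest.approx((rss0 - rss1) / (2 * s2), rel=1e-12)

    def test_invalid_variance(self):
        with pytest.raises(ValueError):
            bayes_factor(1.0, 1.0, 1.0, 0.0)


class TestShrinkageAndMonotonicity:
    def test_shrinkage_and_sign(self, rng):
        for _ in range(60):
            Y = float(rng.choice([-1, 1]) * np.exp(rng.uniform(-3, 3)))
            s2 = float(np.exp(rng.uniform(np.log(1e-4), 0.0)))
            gamma = float(rng.choice([1e-6, 0.005, 0.5]))
            lam = float(np.exp(rng.uniform(np.log(0.1), np.log(1e4))))
            ghat = make_post(Y, s2, gamma, lam).ghat
            assert abs(ghat) <= abs(Y) + 1e-12
            assert ghat == 0.0 or np.sign(ghat) == np.sign(Y)

    def test_kappa_monotone_in_lambda(self):
        kappas = []
        for lam in [0.5, 2.0, 8.0, 32.0]:
            post = make_post(1.0, 0.01, 0.05, lam)
            half = 10 * (abs(post.ghat) + 0.1)
            kappas.append(hpd_credibility(post, HpdGridSpec(-half, half)).kappa)
        assert all(a >= b - 1e-9 for a, b in zip(kappas, kappas[1:]))

    def test_kappa_monotone_in_gamma(self):
        kappas = []
        for gamma in [0.5, 0.05, 0.005, 1e-4]:
            post = make_post(0.4, 0.01, gamma, 5.0)
            half = 10 * (abs(post.ghat) + 0.1)
            kappas.append(hpd_credibility(post, HpdGridSpec(-half, half)).kappa)
        assert all(a >= b - 1e-9 for a, b in zip(kappas, kappas[1:]))
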