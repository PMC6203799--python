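"""Lactin-1 fitting, mixture EM, family comparison, interpolation, sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tpphen import (
    GaussianMixturePair,
    LactinTPC,
    TPPSurface,
    compare_families,
    eval_tpc,
    fit_lactin1,
    fit_mixture_em,
    interpolate_mixture,
    sample_rate,
)


def mixture_sample(rng, n, lam1=0.5, mu=(0.05, 0.10), sigma=(0.005, 0.005)):
    pick = rng.random(n) < lam1
    return np.where(pick, rng.normal(mu[0], sigma[0], n), rng.normal(mu[1], sigma[1], n))


class TestLactin:
    def test_parameter_recovery_noiseless(self):
        true = LactinTPC(rho=0.012, t_max=34.0, delta=5.0)
        temps = np.array([10.0, 15.0, 20.0, 25.0, 29.0, 32.0])
        fit = fit_lactin1(temps, true.rate(temps))
        assert fit.rho == pytest.approx(true.rho, rel=1e-4)
        assert fit.t_max == pytest.approx(true.t_max, rel=1e-4)
        assert fit.delta == pytest.approx(true.delta, rel=1e-4)

    def test_rate_is_zero_at_upper_limit(self):
        tpc = LactinTPC(rho=0.01, t_max=35.0, delta=4.0)
        assert eval_tpc(tpc, 35.0) == 0.0

    def test_known_value(self):
        tpc = LactinTPC(rho=0.01, t_max=35.0, delta=4.0)
        expected = math.exp(0.2) - math.exp(0.35 - 3.75)
        assert eval_tpc(tpc, 20.0) == pytest.approx(expected, abs=1e-12)

    def test_clamped_to_zero_below_cold_crossing(self):
        tpc = LactinTPC(rho=0.15, t_max=35.0, delta=2.0)
        assert eval_tpc(tpc, -40.0) >= 0.0
        # far past t_max the raw form goes negative; the clamp holds
        assert eval_tpc(tpc, 60.0) == 0.0

    def test_too_few_temperatures(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_lactin1([10, 15, 20], [0.1, 0.2, 0.3])


class TestMixtureEM:
    def test_parameter_recovery(self, rng):
        x = mixture_sample(rng, 400)
        fit = fit_mixture_em(x, seed=0)
        assert fit.mu1 == pytest.approx(0.05, abs=0.005)
        assert fit.mu2 == pytest.approx(0.10, abs=0.005)
        assert fit.lambda1 == pytest.approx(0.5, abs=0.1)
        assert fit.lambda1 + fit.lambda2 == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_sample_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_mixture_em(np.full(20, 0.1))

    def test_small_sample_errors(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_mixture_em([0.1, 0.2, 0.3])

    def test_loglik_dominates_single_normal(self, rng):
        x = rng.normal(0.08, 0.01, 300)
        fit = fit_mixture_em(x, seed=0)
        single = stats.norm.logpdf(x, x.mean(), x.std()).sum()
        assert fit.loglik >= single - 1e-6

    def test_em_loglik_trace_monotone(self, rng):
        x = mixture_sample(rng, 200)
        _, trace = fit_mixture_em(x, seed=0, return_trace=True)
        assert np.all(np.diff(trace) >= -1e-7)

    def test_restart_label_invariance(self, rng):
        # after mu-ordering the fit must not depend on the initialization seed
        x = mixture_sample(rng, 400)
        a = fit_mixture_em(x, seed=1)
        b = fit_mixture_em(x, seed=999)
        assert a.mu1 == pytest.approx(b.mu1, abs=1e-6)
        assert a.mu2 == pytest.approx(b.mu2, abs=1e-6)
        assert a.lambda1 == pytest.approx(b.lambda1, abs=1e-6)

    def test_matches_sklearn_reference(self, rng):
        # independent EM implementation as an oracle for the maximized likelihood
        sklearn = pytest.importorskip("sklearn.mixture")
        x = mixture_sample(rng, 500)
        ours = fit_mixture_em(x, seed=0)
        gm = sklearn.GaussianMixture(
            n_components=2, n_init=5, tol=1e-8, reg_covar=1e-12, random_state=0
        ).fit(x[:, None])
        ref_ll = float(gm.score(x[:, None]) * x.size)
        assert ours.loglik == pytest.approx(ref_ll, abs=0.05)
        ref_mu = np.sort(gm.means_.ravel())
        assert ours.mu1 == pytest.approx(ref_mu[0], abs=1e-3)
        assert ours.mu2 == pytest.approx(ref_mu[1], abs=1e-3)


class TestFamilyComparison:
    def test_bimodal_sample_prefers_mixture(self, rng):
        x = mixture_sample(rng, 300)  # components 10 sigma apart
        comp = compare_families(x, seed=0)
        assert comp.best == "mixture2"
        assert comp.mixture2 > comp.weibull
        assert comp.mixture2 > comp.lognormal

    def test_lognormal_sample_scores_close(self, rng):
        x = rng.lognormal(mean=-2.5, sigma=0.3, size=500)
        comp = compare_families(x, seed=0)
        best = max(comp.mixture2, comp.weibull, comp.lognormal)
        assert comp.lognormal >= best - 2.0

    def test_bimodal_grid_mostly_prefers_mixture(self, rng):
        # 45 temperature x stage cells, all generated bimodal
        wins = 0
        for case in range(45):
            mid = 0.05 + 0.004 * (case % 9)
            x = mixture_sample(
                rng, 60, mu=(0.75 * mid, 1.25 * mid), sigma=(0.1 * mid, 0.1 * mid)
            )
            if compare_families(x, seed=case).best == "mixture2":
                wins += 1
        assert wins >= 40


class TestInterpolation:
    @staticmethod
    def surface():
        return TPPSurface(
            stage="E",
            anchors={
                13.0: GaussianMixturePair(0.4, 0.6, 0.04, 0.09, 0.004, 0.006),
                18.0: GaussianMixturePair(0.6, 0.4, 0.08, 0.13, 0.008, 0.010),
                25.0: GaussianMixturePair(0.5, 0.5, 0.10, 0.20, 0.010, 0.015),
            },
        )

    def test_exact_at_anchor(self):
        s = self.surface()
        assert interpolate_mixture(s, 18.0) is s.anchors[18.0]

    def test_midpoint_is_arithmetic_mean(self):
        s = self.surface()
        mid = interpolate_mixture(s, 15.5)
        assert mid.mu1 == pytest.approx(0.06, abs=1e-15)
        assert mid.mu2 == pytest.approx((0.09 + 0.13) / 2, abs=1e-15)
        assert mid.lambda1 == pytest.approx(0.5, abs=1e-12)

    def test_clamps_outside_anchor_range(self):
        s = self.surface()
        assert interpolate_mixture(s, 10.0) is s.anchors[13.0]
        assert interpolate_mixture(s, 30.0) is s.anchors[25.0]

    def test_weights_sum_to_one_everywhere(self):
        s = self.surface()
        for t in np.linspace(13, 25, 37):
            p = interpolate_mixture(s, float(t))
            assert p.lambda1 + p.lambda2 == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(temp=st.floats(13.0, 25.0))
    def test_parameters_lie_between_anchor_values(self, temp):
        s = self.surface()
        temps = s.anchor_temps
        j = int(np.searchsorted(temps, temp, side="right"))
        j = min(max(j, 1), len(temps) - 1)
        lo, hi = s.anchors[float(temps[j - 1])], s.anchors[float(temps[j])]
        p = interpolate_mixture(s, temp)
        for name in ("mu1", "mu2", "sigma1", "sigma2"):
            a, b = sorted((getattr(lo, name), getattr(hi, name)))
            assert a - 1e-12 <= getattr(p, name) <= b + 1e-12

    def test_continuity_near_anchor(self):
        s = self.surface()
        eps = 1e-9
        below = interpolate_mixture(s, 18.0 - eps)
        above = interpolate_mixture(s, 18.0 + eps)
        at = interpolate_mixture(s, 18.0)
        assert below.mu1 == pytest.approx(at.mu1, abs=1e-6)
        assert above.mu1 == pytest.approx(at.mu1, abs=1e-6)


class TestSampleRate:
    MIX = GaussianMixturePair(0.3, 0.7, 0.05, 0.10, 0.005, 0.008)

    def test_component_means(self, rng):
        n = 10**5
        slow = sample_rate(self.MIX, "slow", rng, size=n)
        inter = sample_rate(self.MIX, "intermediate", rng, size=n)
        se_slow = self.MIX.sigma1 / np.sqrt(n)
        assert abs(slow.mean() - self.MIX.mu1) < 3 * se_slow
        mix_mean = 0.3 * 0.05 + 0.7 * 0.10
        mix_sd = np.sqrt(
            0.3 * (0.005**2 + (0.05 - mix_mean) ** 2)
            + 0.7 * (0.008**2 + (0.10 - mix_mean) ** 2)
        )
        assert abs(inter.mean() - mix_mean) < 3 * mix_sd / np.sqrt(n)

    def test_empirical_cdf_matches_analytic(self, rng):
        n = 10**5
        draws = sample_rate(self.MIX, "intermediate", rng, size=n)
        ks = stats.kstest(draws, self.MIX.cdf).statistic
        assert ks < 2 / np.sqrt(n)

    def test_degenerate_mixture_makes_strategies_identical(self, rng):
        mix = GaussianMixturePair(0.5, 0.5, 0.07, 0.07, 0.004, 0.004)
        slow = sample_rate(mix, "slow", rng, size=20000)
        fast = sample_rate(mix, "fast", rng, size=20000)
        assert stats.ks_2samp(slow, fast).pvalue > 0.01

    def test_negative_draws_truncate_to_zero(self, rng):
        mix = GaussianMixturePair(0.5, 0.5, 0.001, 0.002, 0.05, 0.05)
        draws = sample_rate(mix, "intermediate", rng, size=5000)
        assert (draws >= 0).all() and (draws == 0).any()
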