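"""ZINB likelihood, priors, Metropolis-Hastings sampler, posterior summaries."""

import math

import numpy as np
import pytest
import scipy.stats

from burstfish import (
    DataError,
    MCMCConfig,
    ParameterError,
    ZINBBurstEstimator,
    ZINBParams,
    burst_parameters,
    log_posterior,
    run_mcmc,
    sample_zinb,
    summarize_posterior,
    zinb_logpmf,
)
from burstfish.inference import PosteriorChain, _make_log_posterior, _run_chain


class TestZINBLogPmf:
    def test_fully_repressed_zero_mass(self):
        assert zinb_logpmf(0, ZINBParams(1.0, 3.0, 0.5)) == 0.0

    def test_reduces_to_geometric_when_r_is_one(self):
        params = ZINBParams(0.0, 1.0, 0.3)
        k = np.arange(12)
        expected = k * math.log(0.3) + math.log(0.7)
        np.testing.assert_allclose(zinb_logpmf(k, params), expected, rtol=1e-12)

    def test_normalizes_to_one(self):
        """Tail-truncated pmf summation reaches 1 within 1e-9."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            params = ZINBParams(
                omega=rng.uniform(0, 0.95),
                r=rng.uniform(0.1, 15.0),
                p=rng.uniform(0.05, 0.9),
            )
            k_max = 200
            probs = np.exp(zinb_logpmf(np.arange(k_max + 1), params))
            while probs[-1] > 1e-12:
                k_max *= 2
                probs = np.exp(zinb_logpmf(np.arange(k_max + 1), params))
            assert abs(probs.sum() - 1.0) < 1e-9

    def test_negative_k_rejected(self):
        with pytest.raises(ParameterError):
            zinb_logpmf(-1, ZINBParams(0.5, 1.0, 0.5))


def reference_log_posterior(theta, counts):
    """Independent term-by-term oracle built from scipy distributions."""
    omega, r, p = theta
    if not (0 <= omega <= 1 and 0 < p < 1 and r > 0):
        return -np.inf
    ll = 0.0
    for k in counts:
        nb = scipy.stats.nbinom.pmf(k, r, 1.0 - p)  # scipy's p is our 1-p
        prob = (omega if k == 0 else 0.0) + (1 - omega) * nb
        ll += math.log(prob)
    return ll + scipy.stats.halfnorm.logpdf(r, scale=20.0)


class TestLogPosterior:
    def test_outside_support_is_minus_inf(self, small_counts):
        assert log_posterior(np.array([1.2, 1.0, 0.5]), small_counts) == -np.inf
        assert log_posterior(np.array([0.5, -1.0, 0.5]), small_counts) == -np.inf

    def test_matches_independent_summation_oracle(self, small_counts):
        counts = small_counts["count"].to_numpy()[:10]
        rng = np.random.default_rng(3)
        for _ in range(10):
            theta = [rng.uniform(0.05, 0.95), rng.uniform(0.2, 8), rng.uniform(0.1, 0.9)]
            assert log_posterior(np.array(theta), counts) == pytest.approx(
                reference_log_posterior(theta, counts), rel=1e-10
            )

    def test_iid_likelihood_is_additive(self, small_counts):
        counts = small_counts["count"].to_numpy()
        doubled = np.concatenate([counts, counts])
        theta = np.array([0.4, 2.0, 0.6])
        prior = scipy.stats.halfnorm.logpdf(2.0, scale=20.0)
        ll_single = log_posterior(theta, counts) - prior
        ll_double = log_posterior(theta, doubled) - prior
        assert ll_double == pytest.approx(2 * ll_single, rel=1e-12)


class TestMCMCConfig:
    def test_retained_length_arithmetic(self):
        assert MCMCConfig().retained_length == 4000  # (500000-100000)/100
        assert MCMCConfig(n_iter=1001, burn_in=0, thin=10).retained_length == 100

    def test_invalid_configs_rejected(self):
        with pytest.raises(ParameterError):
            MCMCConfig(n_iter=1000, burn_in=1000)
        with pytest.raises(ParameterError):
            MCMCConfig(thin=0)


class TestRunMCMC:
    CFG = MCMCConfig(n_iter=4000, burn_in=1000, thin=5, seed=123)

    def test_same_seed_gives_identical_chain(self, small_counts):
        a = run_mcmc(small_counts, self.CFG)
        b = run_mcmc(small_counts, self.CFG)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.acceptance_rate == b.acceptance_rate

    def test_acceptance_rate_is_nondegenerate(self, small_counts):
        chain = run_mcmc(small_counts, self.CFG)
        assert 0.0 < chain.acceptance_rate < 1.0
        assert chain.samples.shape == (self.CFG.retained_length, 3)
        assert np.isfinite(chain.log_post).all()

    def test_posterior_shift_invariance(self, small_counts):
        """MH depends only on posterior ratios: a constant offset changes nothing."""
        log_post = _make_log_posterior(small_counts["count"].to_numpy())
        shifted = lambda theta: log_post(theta) + 123.456  # noqa: E731
        theta0 = np.array([0.4, 1.5, 0.6])
        s1, _, r1 = _run_chain(log_post, theta0, self.CFG)
        s2, _, r2 = _run_chain(shifted, theta0, self.CFG)
        np.testing.assert_array_equal(s1, s2)
        assert r1 == r2

    def test_all_zero_dataset_is_valid_and_implies_silence(self):
        """All zeros can be explained by omega -> 1 or by a vanishing NB mean
        (the two are not identified against each other), so the sharp
        statement is that the implied ZINB mean concentrates near 0."""
        counts = np.zeros(200, dtype=int)
        chain = run_mcmc(counts, MCMCConfig(n_iter=20000, burn_in=5000, thin=10, seed=1))
        omega, r, p = chain.samples.T
        implied_mean = (1 - omega) * r * p / (1 - p)
        assert np.median(implied_mean) < 0.05
        assert np.percentile(implied_mean, 97.5) < 0.5

    def test_every_retained_sample_is_in_support(self, small_counts):
        chain = run_mcmc(small_counts, self.CFG)
        omega, r, p = chain.samples.T
        assert ((omega >= 0) & (omega <= 1)).all()
        assert (r > 0).all()
        assert ((p > 0) & (p < 1)).all()


class TestSummaries:
    def test_degenerate_chain(self):
        theta = np.array([[0.3, 2.0, 0.5]] * 10)
        chain = PosteriorChain(
            samples=theta,
            log_post=np.zeros(10),
            acceptance_rate=0.5,
            config=MCMCConfig(n_iter=10, burn_in=0, thin=1),
        )
        est = summarize_posterior(chain)
        assert est.map == {"omega": 0.3, "b": 1.0, "f": 2.0}
        for lo, hi in est.ci95.values():
            assert lo == hi

    def test_empty_chain_rejected(self):
        chain = PosteriorChain(
            samples=np.empty((0, 3)),
            log_post=np.empty(0),
            acceptance_rate=0.0,
            config=MCMCConfig(n_iter=10, burn_in=0, thin=1),
        )
        with pytest.raises(DataError):
            summarize_posterior(chain)


class TestBurstParameters:
    def test_even_odds_means_unit_burst(self):
        omega, b, f = burst_parameters(ZINBParams(0.2, 3.0, 0.5))
        assert (omega, b, f) == (0.2, 1.0, 3.0)

    def test_p_equal_one_rejected(self):
        with pytest.raises(ParameterError):
            burst_parameters((0.2, 3.0, 1.0))

    def test_moment_identity_against_sampler(self):
        # E[count] = (1 - omega) * f * b
        params = ZINBParams(0.4, 1.5, 0.6)
        omega, b, f = burst_parameters(params)
        n = 100_000
        df = sample_zinb(params, n, seed=9)
        se = math.sqrt(params.var() / n)
        assert abs(df["count"].mean() - (1 - omega) * f * b) < 3 * se


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        est = ZINBBurstEstimator(n_iter=1000, burn_in=100, thin=5, random_state=3)
        clone_params = est.get_params()
        assert clone_params["n_iter"] == 1000
        est.set_params(thin=10)
        assert est.thin == 10

    def test_fit_exposes_posterior_attributes(self, canonical_params):
        counts = sample_zinb(canonical_params, 500, seed=5)
        est = ZINBBurstEstimator(n_iter=20000, burn_in=4000, thin=20, random_state=0).fit(counts)
        assert set(est.map_) == {"omega", "b", "f"}
        assert 0 < est.acceptance_rate_ < 1
        for lo, hi in est.ci95_.values():
            assert lo <= hi
        # MAP should land near the generating parameters on easy data
        assert est.map_["omega"] == pytest.approx(0.5, abs=0.15)
        assert est.map_["b"] == pytest.approx(0.7 / 0.3, rel=0.5)
        assert np.isfinite(est.score(counts))


class TestCoverage:
    def test_credible_intervals_cover_prior_draws(self):
        """95% CIs cover the truth in >= 90% of prior-drawn synthetic datasets."""
        rng = np.random.default_rng(2024)
        hits = {"omega": 0, "r": 0, "p": 0}
        n_rep = 50
        for i in range(n_rep):
            truth = ZINBParams(
                omega=rng.uniform(0.02, 0.98),
                r=float(abs(rng.normal(0, 20)) + 1e-3),
                p=rng.uniform(0.02, 0.98),
            )
            counts = sample_zinb(truth, 1000, seed=int(rng.integers(2**31)))
            chain = run_mcmc(
                counts, MCMCConfig(n_iter=80000, burn_in=16000, thin=40, seed=i)
            )
            for j, name in enumerate(["omega", "r", "p"]):
                lo, hi = np.percentile(chain.samples[:, j], [2.5, 97.5])
                hits[name] += lo <= getattr(truth, name) <= hi
        for name, h in hits.items():
            assert h >= 0.9 * n_rep, f"{name}: covered {h}/{n_rep}"

    def test_zinb_fit_recovers_telegraph_burst_size(self):
        """Mechanistic cross-check: fitted b within 25% of k_tx / k_off."""
        from burstfish import TelegraphParams, simulate_telegraph

        params = TelegraphParams(k_on=0.5, k_off=20.0, k_tx=200.0, k_deg=1.0)
        counts = simulate_telegraph(params, 2000, 15.0, seed=77)
        est = ZINBBurstEstimator(n_iter=30000, burn_in=6000, thin=25, random_state=1).fit(counts)
        b_true = params.k_tx / params.k_off
        assert est.map_["b"] == pytest.approx(b_true, rel=0.25)
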