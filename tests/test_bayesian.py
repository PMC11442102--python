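"""Likelihood/prior forms, the adaptive Metropolis core, posterior
summaries and chain diagnostics."""

import numpy as np
import pytest

from pvcal.bayesian import (
    PosteriorChain,
    PriorSpec,
    adaptive_metropolis,
    autocorrelation,
    chain_diagnostics,
    effective_sample_size,
    log_likelihood,
    log_prior,
    posterior_summary,
)
from pvcal.frequentist import cost_ols
from pvcal.model import ContractError


class TestLikelihood:
    def test_formula_at_unit_variance(self, noisy_dataset, theta_truth_free):
        n = 3 * 55
        j = cost_ols(theta_truth_free, noisy_dataset)
        ll = log_likelihood(theta_truth_free, 1.0, noisy_dataset)
        assert ll == pytest.approx(-(n / 2) * np.log(2 * np.pi) - j / 2)

    def test_variance_profile_maximized_at_j_over_n(self, noisy_dataset, theta_truth_free):
        n = 3 * 55
        j = cost_ols(theta_truth_free, noisy_dataset)
        s2_star = j / n
        best = log_likelihood(theta_truth_free, s2_star, noisy_dataset)
        for s2 in (0.5 * s2_star, 2.0 * s2_star):
            assert log_likelihood(theta_truth_free, s2, noisy_dataset) < best

    def test_monotone_decreasing_in_cost(self, noisy_dataset, truth_dataset, theta_truth_free):
        # same θ, worse-fitting data ⇒ lower likelihood at fixed σ²
        ll_noisy = log_likelihood(theta_truth_free, 4.0, noisy_dataset)
        ll_clean = log_likelihood(theta_truth_free, 4.0, truth_dataset)
        assert ll_noisy < ll_clean

    def test_rejects_nonpositive_variance(self, noisy_dataset, theta_truth_free):
        with pytest.raises(ContractError):
            log_likelihood(theta_truth_free, 0.0, noisy_dataset)


class TestPrior:
    def setup_method(self):
        self.priors = PriorSpec({"a": (0.0, 2.0), "b": (1.0, 3.0)})

    def test_inside_is_constant(self):
        expected = -(np.log(2.0) + np.log(2.0))
        assert log_prior([1.0, 2.0], self.priors) == pytest.approx(expected)

    def test_outside_is_minus_inf(self):
        assert log_prior([-0.1, 2.0], self.priors) == -np.inf
        assert log_prior([1.0, 3.5], self.priors) == -np.inf

    def test_boundary_counts_inside(self):
        assert np.isfinite(log_prior([0.0, 3.0], self.priors))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ContractError):
            PriorSpec({"a": (2.0, 2.0)})


class TestAdaptiveMetropolisCore:
    def test_recovers_gaussian_moments(self):
        mean = np.array([1.0, -2.0])
        cov = np.array([[1.0, 0.5], [0.5, 2.0]])
        prec = np.linalg.inv(cov)

        def log_target(x):
            d = x - mean
            return -0.5 * float(d @ prec @ d)

        rng = np.random.default_rng(0)
        samples, _, accepted = adaptive_metropolis(
            log_target, np.zeros(2), 30_000, rng, init_proposal_sd=[0.5, 0.5]
        )
        post = samples[5000:]
        for i in range(2):
            ess = effective_sample_size(post[:, i])
            mcse = np.std(post[:, i], ddof=1) / np.sqrt(ess)
            assert abs(post[:, i].mean() - mean[i]) < 3 * mcse
        emp_cov = np.cov(post.T)
        assert np.allclose(emp_cov, cov, rtol=0.25, atol=0.1)
        assert 0.1 < accepted[5000:].mean() < 0.6

    def test_rejects_zero_density_start(self):
        with pytest.raises(ContractError):
            adaptive_metropolis(
                lambda x: -np.inf, np.zeros(1), 10, np.random.default_rng(0), [0.1]
            )


class TestCardiacChain:
    def test_samples_within_prior_box(self, short_chain):
        priors = PriorSpec.from_defaults(short_chain.names)
        lo, hi = priors.arrays()
        assert np.all(short_chain.samples >= lo)
        assert np.all(short_chain.samples <= hi)
        assert np.all(short_chain.sigma2 > 0)

    def test_acceptance_rate_reasonable(self, short_chain):
        post_adapt = short_chain.accepted[short_chain.adapt_start :]
        assert 0.1 < post_adapt.mean() < 0.6

    def test_bit_reproducible(self, short_chain, noisy_dataset):
        from pvcal.bayesian import adaptive_metropolis_sample

        again = adaptive_metropolis_sample(noisy_dataset, n_iter=200, seed=0)
        assert np.array_equal(again.samples, short_chain.samples[:200])

    def test_noise_variance_tracks_truth(self, short_chain):
        # generated with iid sd 2 ⇒ posterior σ² concentrates near 4
        post = short_chain.sigma2[short_chain.burn_in :]
        assert 2.0 < np.median(post) < 8.0


def _chain_from(samples, names=("x",)):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 1:
        samples = samples.T
    n = samples.shape[0]
    return PosteriorChain(
        names=tuple(names),
        samples=samples,
        sigma2=np.ones(n),
        log_post=np.zeros(n),
        accepted=np.ones(n, dtype=bool),
        acceptance_rate=1.0,
        seed=0,
        burn_in=0,
        adapt_start=0,
        adapt_interval=1,
        epsilon=0.0,
    )


class TestPosteriorSummary:
    def test_percentile_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(5000)
        summ = posterior_summary(_chain_from(x))
        lo, hi = np.percentile(np.sort(x), [2.5, 97.5])
        assert summ.loc["x", "ci_lower"] == pytest.approx(lo)
        assert summ.loc["x", "ci_upper"] == pytest.approx(hi)
        assert summ.loc["x", "mean"] == pytest.approx(x.mean())

    def test_symmetric_sample_mode_near_mean(self):
        rng = np.random.default_rng(9)
        x = rng.normal(5.0, 1.0, 20_000)
        summ = posterior_summary(_chain_from(x))
        assert summ.loc["x", "mode"] == pytest.approx(5.0, abs=0.2)

    def test_lognormal_ordering(self):
        rng = np.random.default_rng(10)
        x = rng.lognormal(0.0, 1.0, 20_000)
        summ = posterior_summary(_chain_from(x))
        assert summ.loc["x", "mode"] < summ.loc["x", "median"] < summ.loc["x", "mean"]

    def test_degenerate_marginal(self):
        summ = posterior_summary(_chain_from(np.full(100, 3.0)))
        assert summ.loc["x", "mode"] == 3.0
        assert summ.loc["x", "sd"] == 0.0


class TestCredibleCoverage:
    def test_credible_intervals_contain_truth(self, truth_params, constants, theta_truth_free):
        """Across noisy replicates the 95% credible intervals contain the
        generating parameters in at least ~90% of parameter-replicate
        pairs (reduced-scale replication study)."""
        from pvcal import NoiseSpec, synthesize_dataset
        from pvcal.bayesian import adaptive_metropolis_sample

        hits, total = 0, 0
        for rep in range(8):
            noisy, _ = synthesize_dataset(
                truth_params, constants, NoiseSpec(sigma=2.0, seed=300 + rep)
            )
            chain = adaptive_metropolis_sample(noisy, n_iter=2000, seed=rep)
            summ = posterior_summary(chain)
            for i, name in enumerate(chain.names):
                total += 1
                hits += int(
                    summ.loc[name, "ci_lower"]
                    <= theta_truth_free[i]
                    <= summ.loc[name, "ci_upper"]
                )
        assert hits / total >= 0.85


class TestDiagnostics:
    def test_iid_chain_low_lag1(self):
        rng = np.random.default_rng(11)
        hits = 0
        n = 2000
        for _ in range(40):
            acf = autocorrelation(rng.standard_normal(n), max_lag=1)
            hits += abs(acf[1]) < 2 / np.sqrt(n)
        assert hits >= 36  # ≥ 90% of repeats inside the white-noise band

    def test_ar1_ess_closed_form(self):
        rho, n = 0.9, 60_000
        rng = np.random.default_rng(12)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        innov = np.sqrt(1 - rho**2) * rng.standard_normal(n)
        for k in range(1, n):
            x[k] = rho * x[k - 1] + innov[k]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.2)

    def test_constant_chain_zero_acceptance(self):
        chain = _chain_from(np.full(50, 1.0))
        chain.accepted = np.zeros(50, dtype=bool)
        chain.acceptance_rate = 0.0
        diag = chain_diagnostics(chain)
        assert diag.loc["x", "acceptance_rate"] == 0.0
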