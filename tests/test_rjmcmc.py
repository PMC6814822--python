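"""RJ-MCMC shift sampler: priors, moves, diagnostics, posterior summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from ssdevol import simulate_tree, gelman_rubin, effective_sample_size
from ssdevol.rjmcmc import (
    Shift,
    ShiftConfig,
    ShiftPriors,
    ShiftModel,
    prior_logdensity,
    summarize_posterior,
    _trunc_poisson_logpmf,
)


@pytest.fixture
def small_tree():
    return simulate_tree(20, 10.0, seed=90)


@pytest.fixture
def priors():
    return ShiftPriors(k_lambda=15.0, theta_mean=0.0, theta_sd=10.0,
                       log_alpha_mu=math.log(0.2), log_sigma2_mu=math.log(5.0))


class TestPrior:
    def test_k0_config(self, small_tree, priors):
        cfg = ShiftConfig((), theta0=1.0, alpha=0.2, sigma2=5.0)
        lp = prior_logdensity(cfg, small_tree, priors)
        B = len(small_tree.branch_ids())
        expected = (
            _trunc_poisson_logpmf(0, 15.0, B)
            + stats.norm.logpdf(1.0, 0.0, 10.0)
            + stats.norm.logpdf(math.log(0.2), priors.log_alpha_mu, 1.5)
            + stats.norm.logpdf(math.log(5.0), priors.log_sigma2_mu, 1.5)
        )
        assert lp == pytest.approx(expected, abs=1e-10)

    def test_branch_exchangeability(self, small_tree, priors):
        bids = small_tree.branch_ids()
        cfg1 = ShiftConfig((Shift(bids[0], 0.3, 2.0),), 0.0, 0.2, 5.0)
        cfg2 = ShiftConfig((Shift(bids[7], 0.9, 2.0),), 0.0, 0.2, 5.0)
        assert prior_logdensity(cfg1, small_tree, priors) == pytest.approx(
            prior_logdensity(cfg2, small_tree, priors)
        )

    def test_double_shift_on_branch_rejected(self, small_tree, priors):
        b = small_tree.branch_ids()[0]
        cfg = ShiftConfig((Shift(b, 0.1, 1.0), Shift(b, 0.6, -1.0)), 0.0, 0.2, 5.0)
        assert prior_logdensity(cfg, small_tree, priors) == -math.inf

    def test_k_marginal_sums_to_one(self, small_tree):
        B = len(small_tree.branch_ids())
        total = sum(math.exp(_trunc_poisson_logpmf(k, 15.0, B)) for k in range(B + 1))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestDiagnostics:
    def test_identical_chains_rhat_one(self, rng):
        x = rng.standard_normal(500)
        with pytest.warns(UserWarning):
            r = gelman_rubin(np.vstack([np.ones(100), np.ones(100)]))
        assert r == 1.0
        assert gelman_rubin(np.vstack([x, x])) == pytest.approx(1.0, abs=1e-6)

    def test_iid_chains_rhat_near_one(self):
        rng = np.random.default_rng(91)
        chains = rng.standard_normal((2, 5000))
        assert gelman_rubin(chains) < 1.01

    def test_divergent_chains_rhat_large(self):
        rng = np.random.default_rng(92)
        chains = np.vstack([rng.normal(0, 1, 5000), rng.normal(10, 1, 5000)])
        assert gelman_rubin(chains) > 1.5

    def test_ess_iid(self):
        rng = np.random.default_rng(93)
        ess = effective_sample_size(rng.standard_normal(2000))
        assert 1600 <= ess <= 2400

    def test_ess_ar1(self):
        rng = np.random.default_rng(94)
        rho, n = 0.9, 2000
        x = np.zeros(n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + math.sqrt(1 - rho**2) * rng.standard_normal()
        truth = n * (1 - rho) / (1 + rho)  # ~105
        ess = effective_sample_size(x)
        assert truth / 2 <= ess <= truth * 2

    def test_ess_degenerate_traces(self):
        with pytest.warns(UserWarning):
            assert effective_sample_size(np.ones(50)) == 50.0
        # strongly anti-correlated trace is capped at n, not inflated past it
        alt = np.tile([1.0, -1.0], 25)
        assert effective_sample_size(alt) <= 50.0

    def test_short_trace_error(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.arange(5))

    def test_matches_arviz_on_smooth_trace(self):
        """Cross-check ESS/R-hat against an independent implementation."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(95)
        x = np.zeros((2, 2000))
        for c in range(2):
            for i in range(1, 2000):
                x[c, i] = 0.5 * x[c, i - 1] + rng.standard_normal()
        ours = sum(effective_sample_size(x[c]) for c in range(2))
        assert ours == pytest.approx(float(az.ess(x)), rel=0.25)
        assert gelman_rubin(x) == pytest.approx(float(az.rhat(x)), abs=0.01)


class TestSampler:
    def test_same_seed_identical_traces(self, small_tree, rng):
        y = rng.normal(0, 5, small_tree.n_tips)
        m = ShiftModel(small_tree, y)
        r1 = m.run(n_gens=2000, thin=10, n_chains=2, seed=7)
        r2 = m.run(n_gens=2000, thin=10, n_chains=2, seed=7)
        for c in range(2):
            for k in r1.traces[c]:
                np.testing.assert_array_equal(r1.traces[c][k], r2.traces[c][k])

    def test_pp_sum_equals_mean_k(self, small_tree, rng):
        y = rng.normal(0, 5, small_tree.n_tips)
        run = ShiftModel(small_tree, y).run(n_gens=5000, thin=10, n_chains=2, seed=8)
        post = summarize_posterior(run, burn_in=0.3)
        assert post.branch_pp.sum() == pytest.approx(post.mean_k, abs=1e-9)

    def test_threshold_boundary(self, small_tree, rng):
        y = rng.normal(0, 5, small_tree.n_tips)
        run = ShiftModel(small_tree, y).run(n_gens=4000, thin=10, n_chains=2, seed=9)
        post = summarize_posterior(run, pp_threshold=0.5)
        assert all(post.shifts["pp"] > 0.5)
        assert set(post.shifts["branch_id"]) == set(
            post.branch_pp.index[post.branch_pp > 0.5]
        )

    def test_birth_death_balance_on_prior(self, small_tree, rng):
        """At stationarity under the prior, birth and death rates agree."""
        y = rng.normal(0, 5, small_tree.n_tips)
        run = ShiftModel(small_tree, y, prior_only=True).run(
            n_gens=30_000, thin=30, n_chains=1, seed=10
        )
        (b_acc, b_prop) = run.acceptance[0]["birth"]
        (d_acc, d_prop) = run.acceptance[0]["death"]
        rb, rd = b_acc / b_prop, d_acc / d_prop
        se = math.sqrt(rb * (1 - rb) / b_prop + rd * (1 - rd) / d_prop)
        assert abs(rb - rd) < 4 * se

    def test_fixed_dimension_theta_posterior_matches_conjugate(self):
        """Detailed-balance check: with K fixed at 1 and alpha/sigma^2 held,
        the sampled optima must match the exact conjugate-normal posterior."""
        tree = simulate_tree(5, 4.0, seed=96)
        rng = np.random.default_rng(97)
        y = rng.normal(2.0, 3.0, 5)
        priors = ShiftPriors(theta_mean=0.0, theta_sd=5.0,
                             log_alpha_mu=math.log(0.5), log_sigma2_mu=math.log(4.0))
        b = [v for v in tree.branch_ids() if v >= tree.n_tips][0]
        init = ShiftConfig((Shift(b, 0.5, 0.0),), theta0=0.0,
                           alpha=0.5, sigma2=4.0)
        model = ShiftModel(tree, y, priors=priors)
        run = model.run(
            n_gens=120_000, thin=10, n_chains=1, seed=11, init=init,
            move_weights={"birth": 0, "death": 0, "relocate": 0,
                          "theta": 1.0, "alpha": 0, "sigma2": 0},
        )
        draws0 = np.array([c.theta0 for c in run.samples[0][1000:]])
        draws1 = np.array([c.shifts[0].theta for c in run.samples[0][1000:]])
        # exact posterior: y ~ N(W theta, sigma2 V0), theta ~ N(0, 5^2 I)
        from ssdevol.ou import ou_vcv

        mu = model.lik.mean(init)  # theta = 0 -> mean 0; need design columns
        W = np.zeros((5, 2))
        one_cfg = ShiftConfig((Shift(b, 0.5, 1.0),), theta0=0.0, alpha=0.5, sigma2=4.0)
        W[:, 1] = model.lik.mean(one_cfg)
        zero_cfg = ShiftConfig((Shift(b, 0.5, 0.0),), theta0=1.0, alpha=0.5, sigma2=4.0)
        W[:, 0] = model.lik.mean(zero_cfg)
        V = ou_vcv(tree, 0.5, 4.0)
        prior_prec = np.eye(2) / 25.0
        post_prec = W.T @ np.linalg.solve(V, W) + prior_prec
        post_cov = np.linalg.inv(post_prec)
        post_mean = post_cov @ (W.T @ np.linalg.solve(V, y))
        for draws, mean, var in (
            (draws0, post_mean[0], post_cov[0, 0]),
            (draws1, post_mean[1], post_cov[1, 1]),
        ):
            thinned = draws[::10]
            p = stats.kstest(thinned, "norm", args=(mean, math.sqrt(var))).pvalue
            assert p > 0.01

    def test_empty_burn_in_error(self, small_tree, rng):
        y = rng.normal(0, 5, small_tree.n_tips)
        run = ShiftModel(small_tree, y).run(n_gens=200, thin=100, n_chains=2, seed=12)
        with pytest.raises(ValueError):
            summarize_posterior(run, burn_in=0.99)
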