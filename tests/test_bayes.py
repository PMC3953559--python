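"""MCMC machinery: log posterior, sampler correctness, DIC, diagnostics."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

import hdbayes as hb
from hdbayes.bayes import MCMCChains, log_likelihood
from hdbayes.datasets import TreeDataset
from hdbayes.exceptions import DomainError, ValidationError
from hdbayes.models import predict_height


def empty_dataset() -> TreeDataset:
    return TreeDataset(dbh=np.array([]), height=np.array([]))


def chains_from_array(arr, param_names=("a", "b", "c"), model_id="weibull"):
    """Wrap a raw (chain, draw, p+1) array as MCMCChains for summary tests."""
    arr = np.asarray(arr, dtype=float)
    cfg = hb.MCMCConfig(
        n_iterations=arr.shape[1] + 1, n_burn_in=1, thin=1, n_chains=arr.shape[0]
    )
    return MCMCChains(
        draws=arr,
        param_names=tuple(param_names),
        model_id=model_id,
        prior=hb.uninformative_prior(model_id),
        config=cfg,
    )


class TestLogPosterior:
    def test_empty_dataset_is_prior_only(self):
        prior = hb.uninformative_prior("weibull")
        v = np.array([20.0, 0.07, 0.85, 1.2])
        lp = hb.log_posterior(empty_dataset(), "weibull", v, prior)
        expected = float(
            np.sum(stats.norm.logpdf(v[:3], 0.0, math.sqrt(1000.0)))
        ) + float(stats.gamma.logpdf(1.0 / v[3] ** 2, a=0.001, scale=1000.0))
        assert lp == pytest.approx(expected, rel=1e-12)

    def test_single_on_curve_observation(self):
        theta = (26.58, 0.07, 0.85)
        d = 16.0
        ds = TreeDataset(
            dbh=np.array([d]), height=np.array([predict_height("weibull", theta, d)])
        )
        prior = hb.uninformative_prior("weibull")
        v = np.array([*theta, 1.0])
        lp = hb.log_posterior(ds, "weibull", v, prior)
        lp_prior = hb.log_posterior(empty_dataset(), "weibull", v, prior)
        assert lp - lp_prior == pytest.approx(math.log(1.0 / math.sqrt(2 * math.pi)))

    def test_equal_sse_gives_equal_posterior(self):
        # two heights symmetric about the curve leave the likelihood
        # unchanged when the residual signs flip
        theta = (26.58, 0.07, 0.85)
        d = np.array([10.0, 20.0])
        mu = predict_height("weibull", theta, d)
        prior = hb.uninformative_prior("weibull")
        up = TreeDataset(dbh=d, height=mu + 0.7)
        dn = TreeDataset(dbh=d, height=mu - 0.7)
        v = np.array([*theta, 1.1])
        assert hb.log_posterior(up, "weibull", v, prior) == pytest.approx(
            hb.log_posterior(dn, "weibull", v, prior), rel=1e-12
        )

    def test_sigma_must_be_positive(self):
        prior = hb.uninformative_prior("weibull")
        with pytest.raises(DomainError):
            hb.log_posterior(
                empty_dataset(), "weibull", [20.0, 0.07, 0.85, 0.0], prior
            )

    def test_wrong_length_rejected(self):
        prior = hb.uninformative_prior("weibull")
        with pytest.raises(ValidationError):
            hb.log_posterior(empty_dataset(), "weibull", [1.0, 2.0], prior)


class TestSamplerContracts:
    @pytest.mark.parametrize(
        "iters, burn, thin", [(100, 10, 1), (101, 10, 3), (3000, 500, 7), (50, 49, 5)]
    )
    def test_retained_count_formula(self, iters, burn, thin):
        cfg = hb.MCMCConfig(
            n_iterations=iters, n_burn_in=burn, thin=thin, n_chains=1, seed=0
        )
        assert cfg.n_retained == (iters - burn) // thin
        if cfg.n_retained > 0:
            ch = hb.run_mcmc(empty_dataset(), "power_law",
                             prior=hb.PriorSpec(params={"a": (0, 5), "b": (0, 5)}),
                             config=cfg)
            assert ch.draws.shape == (1, cfg.n_retained, 3)

    def test_seed_determinism(self, data1_dataset):
        cfg = hb.MCMCConfig(n_iterations=2000, n_burn_in=500, seed=42)
        a = hb.run_mcmc(data1_dataset, "weibull", config=cfg)
        b = hb.run_mcmc(data1_dataset, "weibull", config=cfg)
        np.testing.assert_array_equal(a.draws, b.draws)
        c = hb.run_mcmc(data1_dataset, "weibull", config=cfg.with_seed(43))
        assert not np.array_equal(a.draws, c.draws)

    def test_all_draws_finite_sigma_positive(self, data1_dataset):
        ch = hb.run_mcmc(
            data1_dataset, "weibull",
            config=hb.MCMCConfig(n_iterations=3000, n_burn_in=500, seed=9),
        )
        assert np.all(np.isfinite(ch.draws))
        assert np.all(ch.draws[:, :, -1] > 0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            hb.MCMCConfig(n_iterations=100, n_burn_in=100)
        with pytest.raises(ValidationError):
            hb.MCMCConfig(thin=0)
        with pytest.raises(ValidationError):
            hb.MCMCConfig(n_chains=0)

    def test_prior_mismatch_rejected(self, data1_dataset):
        prior = hb.uninformative_prior("power_law")
        with pytest.raises(ValidationError):
            hb.run_mcmc(data1_dataset, "weibull", prior=prior)


class TestSamplerTargets:
    """Does the chain actually sample the distribution it claims to?"""

    def test_prior_recovery_on_empty_data(self):
        # with no data the posterior is the prior; check both update paths
        prior = hb.PriorSpec(params={"a": (0, 10.0), "b": (0, 10.0), "c": (0, 10.0)})
        for lg in (True, False):
            ch = hb.run_mcmc(
                empty_dataset(), "weibull", prior=prior,
                config=hb.MCMCConfig(
                    n_iterations=20_000, n_burn_in=4_000, thin=2, seed=4,
                    linear_gibbs=lg,
                ),
            )
            pooled = ch.pooled()[:, :3]
            assert np.all(np.abs(pooled.mean(axis=0)) < 0.9)
            assert np.all(np.abs(pooled.std(axis=0) - 10.0) < 0.9)

    def test_detailed_balance_against_prior(self):
        # frozen-adaptation random-walk chain on a prior-only target must
        # reproduce that prior (Kolmogorov-Smirnov at alpha = 0.01)
        prior = hb.PriorSpec(params={"a": (2.0, 3.0), "b": (-1.0, 0.5)})
        ch = hb.run_mcmc(
            empty_dataset(), "power_law", prior=prior,
            config=hb.MCMCConfig(
                n_iterations=60_000, n_burn_in=10_000, thin=25, n_chains=1,
                seed=12, linear_gibbs=False,
            ),
        )
        pooled = ch.pooled()
        for j, (m, s) in enumerate([(2.0, 3.0), (-1.0, 0.5)]):
            p = stats.kstest(pooled[:, j], "norm", args=(m, s)).pvalue
            assert p > 0.01

    def test_matches_conjugate_posterior_in_mh_mode(self):
        # straight line through breast height, b and sigma known: the
        # posterior of the slope is available in closed form
        rng = np.random.default_rng(0)
        d = rng.uniform(5, 30, 200)
        sigma = 1.5
        y = 1.3 + 0.8 * d + rng.normal(0, sigma, 200)
        ds = TreeDataset(dbh=d, height=y)
        m0, s0 = 0.0, 10.0
        prec = (d @ d) / sigma**2 + 1 / s0**2
        mean = ((d @ (y - 1.3)) / sigma**2 + m0 / s0**2) / prec
        sd = prec**-0.5
        prior = hb.PriorSpec(params={"a": (m0, s0), "b": (0.0, 1.0)})
        ch = hb.run_mcmc(
            ds, "power_law", prior=prior, fixed={"b": 1.0}, fixed_sigma=sigma,
            config=hb.MCMCConfig(
                n_iterations=20_000, n_burn_in=4_000, thin=2, seed=9,
                linear_gibbs=False,
            ),
        )
        a = ch.pooled()[:, 0]
        mc_se = 3 * sd / math.sqrt(200)  # conservative effective size
        assert abs(a.mean() - mean) < mc_se
        assert abs(a.std(ddof=1) - sd) < 3 * sd / math.sqrt(100)


class TestSummaries:
    def test_constant_chain_summary(self):
        arr = np.full((1, 50, 4), 0.0)
        arr[0, :, 0] = 26.58
        arr[0, :, 3] = 1.0
        s = hb.summarize_posterior(chains_from_array(arr))
        est = s.estimates["a"]
        assert est.mean == pytest.approx(26.58, rel=1e-12)
        assert est.sd == pytest.approx(0.0, abs=1e-12)
        assert (est.ci_low, est.ci_high) == (26.58, 26.58)

    def test_normal_draw_interval_matches_quantiles(self):
        rng = np.random.default_rng(3)
        arr = np.zeros((1, 1_000_000, 2))
        arr[0, :, 0] = rng.standard_normal(1_000_000)
        arr[0, :, 1] = 1.0
        s = hb.summarize_posterior(
            chains_from_array(arr, param_names=("a",), model_id="power_law"),
            check_convergence=False,
        )
        est = s.estimates["a"]
        assert est.ci_low == pytest.approx(-1.96, abs=0.02)
        assert est.ci_high == pytest.approx(1.96, abs=0.02)

    def test_empty_chain_rejected(self):
        with pytest.raises(ValidationError):
            chains_from_array(np.empty((1, 0, 4)))


class TestDIC:
    def test_degenerate_chain_has_zero_pd(self, data1_dataset):
        theta = np.array([26.58, 0.07, 0.85, 1.155])
        arr = np.tile(theta, (1, 200, 1))
        ch = chains_from_array(arr)
        dbar, dhat, pd_, dic = hb.compute_dic(ch, data1_dataset)
        assert pd_ == pytest.approx(0.0, abs=1e-8)
        assert dic == pytest.approx(dhat, abs=1e-8)
        assert dhat == pytest.approx(
            -2 * log_likelihood(data1_dataset, "weibull", theta[:3], theta[3])
        )

    def test_identity_pd_equals_dbar_minus_dhat(self, data1_dataset):
        ch = hb.run_mcmc(
            data1_dataset, "weibull",
            config=hb.MCMCConfig(n_iterations=3000, n_burn_in=500, seed=5),
        )
        dbar, dhat, pd_, dic = hb.compute_dic(ch, data1_dataset)
        assert pd_ == pytest.approx(dbar - dhat, rel=1e-12)
        assert dic == pytest.approx(dbar + pd_, rel=1e-12)

    def test_effective_parameters_near_one_for_mean_model(self):
        # Gaussian mean model with known sigma: pD should approach 1
        rng = np.random.default_rng(2)
        ds = TreeDataset(
            dbh=rng.uniform(5, 30, 1000), height=10 + rng.normal(0, 1.0, 1000)
        )
        prior = hb.PriorSpec(params={"a": (0, 31.6), "b": (0, 31.6)})
        ch = hb.run_mcmc(
            ds, "power_law", prior=prior, fixed={"b": 0.0}, fixed_sigma=1.0,
            config=hb.MCMCConfig(n_iterations=20_000, n_burn_in=4_000, thin=2, seed=2),
        )
        _, _, pd_, _ = hb.compute_dic(ch, ds)
        assert pd_ == pytest.approx(1.0, abs=0.2)


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(8)
        arr = rng.standard_normal((2, 4000, 4))
        arr[:, :, 3] = np.abs(arr[:, :, 3]) + 0.5
        rhats = hb.gelman_rubin(chains_from_array(arr))
        assert all(abs(r - 1.0) < 0.05 for r in rhats.values())

    def test_disjoint_constant_chains_diverge(self):
        arr = np.zeros((2, 100, 4))
        arr[1, :, :] = 5.0
        arr[:, :, 3] = 1.0
        rhats = hb.gelman_rubin(chains_from_array(arr))
        assert rhats["a"] == float("inf")

    def test_single_chain_rejected(self):
        arr = np.zeros((1, 100, 4))
        arr[:, :, 3] = 1.0
        with pytest.raises(ValidationError):
            hb.gelman_rubin(chains_from_array(arr))

    def test_agrees_with_arviz_split_rhat(self, data1_dataset):
        az = pytest.importorskip("arviz")
        ch = hb.run_mcmc(
            data1_dataset, "weibull",
            config=hb.MCMCConfig(n_iterations=6000, n_burn_in=1000, seed=3),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mine = hb.gelman_rubin(ch)
            names = list(ch.param_names) + ["sigma"]
            theirs = {
                n: float(az.rhat(ch.draws[:, :, j]))
                for j, n in enumerate(names)
            }
        for n in names:
            assert mine[n] == pytest.approx(theirs[n], abs=0.05)
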