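"""Savage-Dickey test, power studies and thermodynamic integration."""

import math

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import gamma as gamma_dist

from mscflow import (PriorSpec, TwoSpeciesModelSpec, marginal_likelihood_gq,
                     power_posterior_evidence, power_study, run_mcmc,
                     savage_dickey, simulate_diff_counts)
from mscflow.models import ModelError


@pytest.fixture(scope="module")
def prior_trace():
    priors = PriorSpec.default("IM", migration_on="w", thetaB=0.01)
    return run_mcmc(None, "IM", priors, iterations=24_000, burnin=1000,
                    thin=2, seed=101)


class TestSavageDickey:
    def test_prior_only_bayes_factor_near_one(self, prior_trace):
        res = savage_dickey(prior_trace, epsilon=0.001)
        assert res.B10 == pytest.approx(1.0, abs=0.15)
        assert not res.capped

    def test_prior_null_is_gamma_cdf(self, prior_trace):
        """Independent closed form: P(M < eps) from the prior CDF, mapping
        eps to the w scale through thetaB."""
        eps = 0.001
        res = savage_dickey(prior_trace, epsilon=eps)
        a, b = 2.0, 1.0  # w ~ G(2, 1)
        z = b * (4.0 * eps / 0.01)
        # regularized lower incomplete gamma via the series-free route
        expect = float(gamma_dist.cdf(4.0 * eps / 0.01, a, scale=1.0 / b))
        manual = 1.0 - math.exp(-z) * (1.0 + z)  # closed form for shape 2
        assert res.prior_null == pytest.approx(expect, rel=1e-12)
        assert res.prior_null == pytest.approx(manual, rel=1e-12)

    def test_capping_rule(self, prior_trace):
        # a trace with no posterior mass below epsilon gets the pseudo-count
        trimmed = prior_trace
        keep = trimmed.samples[trimmed.samples["mig"] > 1.0].reset_index(
            drop=True)
        import dataclasses
        capped_trace = dataclasses.replace(trimmed, samples=keep)
        res = savage_dickey(capped_trace, epsilon=0.001)
        assert res.capped
        assert res.posterior_null == pytest.approx(0.5 / len(keep))

    def test_epsilon_validation(self, prior_trace):
        with pytest.raises(ModelError):
            savage_dickey(prior_trace, epsilon=0.0)
        with pytest.raises(ModelError):
            savage_dickey(prior_trace, epsilon=1e3)  # beyond prior support

    def test_strong_flow_detected(self):
        """Correctly specified analysis of data with substantial gene flow
        gives decisive support (B10 > 100).

        The chain starts at the MLE (the IIM posterior is bimodal) and the
        posterior sample is large enough that the pseudo-count bound on B10
        (prior null mass times twice the sample size) can clear 100.
        """
        truth = TwoSpeciesModelSpec(family="IIM", w=130.0, tauT=0.0015,
                                    tauR=0.004, thetaA=0.002, thetaR=0.002)
        rng = np.random.default_rng(55)
        ds = simulate_diff_counts(truth, 2000, 1000, rng)
        priors = PriorSpec.default("IIM", migration_on="M", thetaB=0.01)
        from mscflow import mle_init
        tr = run_mcmc(ds, "IIM", priors, iterations=26_000, burnin=2000,
                      thin=2, seed=56,
                      init=mle_init(ds, "IIM", priors, seed=55))
        res = savage_dickey(tr, epsilon=0.01)
        assert res.B10 > 100

    def test_b10_invariant_to_thinning(self, prior_trace):
        import dataclasses
        full = savage_dickey(prior_trace, epsilon=0.01)
        thin = dataclasses.replace(
            prior_trace, samples=prior_trace.samples.iloc[::5].reset_index(
                drop=True))
        thinned = savage_dickey(thin, epsilon=0.01)
        assert thinned.B10 == pytest.approx(full.B10, rel=0.2)


class TestPowerStudy:
    def test_single_replicate_power_is_binary(self):
        truth = TwoSpeciesModelSpec(family="IM", w=80.0, tauR=0.004,
                                    thetaA=0.002, thetaR=0.002)
        priors = PriorSpec.default("IM", migration_on="w", thetaB=0.01)
        ps = power_study(truth, "IM", priors, L=300, n=500, replicates=1,
                         seed=3, iterations=3000, burnin=600)
        assert ps.power in (0.0, 1.0)
        assert ps.replicates == 1


class TestEvidence:
    def test_empty_data_evidence_is_one(self):
        priors = PriorSpec.default("IM")
        logz, table = marginal_likelihood_gq(None, "IM", priors, K=4)
        assert logz == 0.0
        assert table.empty

    def test_conjugate_toy_matches_closed_form(self):
        """Poisson counts with a gamma prior on the rate: the evidence is a
        negative-binomial product available in closed form."""
        a, b = 3.0, 2.0
        rng = np.random.default_rng(1)
        xs = rng.poisson(1.7, size=12)
        S, N = int(xs.sum()), xs.size
        logz_true = (a * math.log(b) - gammaln(a) + gammaln(a + S)
                     - (a + S) * math.log(b + N) - gammaln(xs + 1.0).sum())

        lfac = gammaln(xs + 1.0).sum()

        def loglik_mu(mu: float) -> float:
            return float(S * math.log(mu) - N * mu - lfac)

        def chain(beta: float, seed: int):
            # conjugate power posterior is Gamma(a + beta*S, b + beta*N)
            r = np.random.default_rng(seed)
            return r.gamma(a + beta * S, 1.0 / (b + beta * N), size=4000)

        logz, _ = power_posterior_evidence(loglik_mu, chain, K=16, seed=5)
        assert logz == pytest.approx(float(logz_true), abs=0.05)

    def test_seed_stability(self):
        """Marginal-likelihood estimates agree across seeds on a small
        fixture dataset."""
        truth = TwoSpeciesModelSpec(family="IM", w=80.0, tauR=0.004,
                                    thetaA=0.002, thetaR=0.002)
        rng = np.random.default_rng(7)
        ds = simulate_diff_counts(truth, 50, 500, rng)
        priors = PriorSpec.default("IM", migration_on="w")
        kw = dict(K=8, iterations=6000, burnin=1200, thin=2)
        z1, _ = marginal_likelihood_gq(ds, "IM", priors, seed=1, **kw)
        z2, _ = marginal_likelihood_gq(ds, "IM", priors, seed=2, **kw)
        assert abs(z1 - z2) < 0.1
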