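"""Likelihood, MLE and MCMC machinery for the two-species families."""

import math

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from mscflow import (PriorSpec, TwoSpeciesModelSpec,
                     fit_mle, hpd_interval, loglik, run_mcmc,
                     simulate_diff_counts, summarize)
from mscflow.inference import McmcTrace
from mscflow.models import ModelError
from mscflow.pmf import diff_count_pmf_quad


@pytest.fixture(scope="module")
def im_data():
    truth = TwoSpeciesModelSpec(family="IM", w=80.0, tauR=0.004,
                                thetaA=0.002, thetaR=0.002)
    rng = np.random.default_rng(77)
    return truth, simulate_diff_counts(truth, 800, 1000, rng)


class TestLoglik:
    def test_duplicated_dataset_doubles_loglik(self, im_data):
        truth, ds = im_data
        assert loglik(ds + ds, truth) == pytest.approx(2 * loglik(ds, truth),
                                                       rel=1e-12)

    def test_matches_bruteforce_quadrature(self, msci_base):
        rng = np.random.default_rng(3)
        ds = simulate_diff_counts(msci_base, 10, 500, rng)
        direct = sum(math.log(diff_count_pmf_quad(int(x), int(n), msci_base))
                     for x, n in zip(ds.x, ds.n))
        assert loglik(ds, msci_base) == pytest.approx(direct, abs=1e-8)

    def test_truth_beats_perturbation_on_average(self, im_data):
        truth, _ = im_data
        worse = truth.with_params(tauR=0.006)
        rng = np.random.default_rng(11)
        wins = 0
        for _ in range(12):
            ds = simulate_diff_counts(truth, 400, 1000, rng)
            wins += loglik(ds, truth) > loglik(ds, worse)
        assert wins >= 10  # KL inequality, in expectation


class TestMle:
    def test_parameter_recovery_large_L(self):
        truth = TwoSpeciesModelSpec(family="IM", w=80.0, tauR=0.004,
                                    thetaA=0.002, thetaR=0.002)
        rng = np.random.default_rng(8)
        ds = simulate_diff_counts(truth, 10_000, 1000, rng)
        params, _, _ = fit_mle(ds, "IM", restarts=5, seed=2)
        assert params["tauR"] == pytest.approx(0.004, rel=0.10)
        assert params["thetaR"] == pytest.approx(0.002, rel=0.10)

    def test_zero_migration_truth_recovers_boundary(self):
        truth = TwoSpeciesModelSpec(family="none", tauR=0.004, thetaA=0.002,
                                    thetaR=0.002)
        rng = np.random.default_rng(9)
        ds = simulate_diff_counts(truth, 3000, 1000, rng)
        params, _, _ = fit_mle(ds, "IM", restarts=4, seed=5)
        assert params["w"] * 0.01 / 4 < 0.01  # M-hat ~ 0

    def test_mle_approaches_pseudo_true_under_misspecification(self,
                                                               msci_base):
        from mscflow import fit_pseudo_true
        rng = np.random.default_rng(10)
        ds = simulate_diff_counts(msci_base, 40_000, 1000, rng)
        params, _, _ = fit_mle(ds, "IIM", restarts=5, seed=6,
                               equal_theta=True)
        star = fit_pseudo_true(msci_base, "IIM", 1000, restarts=5, seed=6)
        assert params["w"] == pytest.approx(star.params["w"], rel=0.15)
        assert params["tauT"] == pytest.approx(star.params["tauT"], rel=0.10)


class TestMcmc:
    def test_prior_only_run_recovers_prior_means(self):
        priors = PriorSpec.default("IM")
        tr = run_mcmc(None, "IM", priors, iterations=16_000, burnin=1000,
                      thin=3, seed=21)
        s = summarize(tr).table
        assert s.loc["mig", "mean"] == pytest.approx(0.2, abs=0.02)
        assert s.loc["tauR", "mean"] == pytest.approx(0.02, abs=0.002)
        assert s.loc["thetaA", "mean"] == pytest.approx(0.01, abs=0.001)

    def test_seed_determinism(self, im_data):
        _, ds = im_data
        priors = PriorSpec.default("IM")
        kw = dict(iterations=600, burnin=100, thin=2, seed=33)
        a = run_mcmc(ds, "IM", priors, **kw)
        b = run_mcmc(ds, "IM", priors, **kw)
        assert a.samples.equals(b.samples)

    def test_single_population_grid_oracle(self):
        """Posterior for a single population size from within-population
        pair counts matches a dense-grid posterior on its mean.

        With the divergence time pinned at ~0 the pair coalesces at rate
        2/thetaR immediately, so the data inform thetaR alone.
        """
        theta_true = 0.004
        spec = TwoSpeciesModelSpec(family="none", tauR=1e-9,
                                   thetaA=theta_true, thetaR=theta_true)
        rng = np.random.default_rng(4)
        ds = simulate_diff_counts(spec, 400, 1000, rng)
        priors = PriorSpec(gammas={"thetaA": (2, 200), "thetaR": (2, 200),
                                   "tauR": (2, 2e9)})  # tauR pinned near 0
        tr = run_mcmc(ds, "none", priors, iterations=30_000, burnin=2_000,
                      thin=3, seed=5)
        from mscflow.pmf import diff_count_logpmf
        xs_u, counts = np.unique(ds.x, return_counts=True)
        grid = np.linspace(2e-4, 0.02, 4000)
        ll = np.array([counts @ diff_count_logpmf(xs_u, 1000,
                                                  spec.with_params(thetaR=g))
                       for g in grid])
        logpost = ll + gamma_dist.logpdf(grid, 2, scale=1 / 200)
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        grid_mean = float((grid * w).sum())
        post_mean = summarize(tr).table.loc["thetaR", "mean"]
        assert post_mean == pytest.approx(grid_mean, rel=0.01)


class TestSummaries:
    def test_constant_trace_degenerate_hpd(self):
        lo, hi = hpd_interval(np.full(500, 3.14))
        assert lo == hi == pytest.approx(3.14)

    def test_normal_draws_hpd(self, rng):
        draws = rng.normal(size=200_000)
        lo, hi = hpd_interval(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.04)
        assert hi == pytest.approx(1.96, abs=0.04)

    def test_hpd_no_wider_than_equal_tail(self, rng):
        draws = rng.gamma(2.0, 0.5, size=50_000)
        lo, hi = hpd_interval(draws, 0.95)
        et = np.quantile(draws, [0.025, 0.975])
        assert (hi - lo) <= (et[1] - et[0]) + 1e-12

    def test_trace_and_summary_files(self, im_data, tmp_path):
        _, ds = im_data
        priors = PriorSpec.default("IM")
        tr = run_mcmc(ds, "IM", priors, iterations=800, burnin=200, thin=4,
                      seed=44)
        p = tmp_path / "trace.tsv"
        tr.to_tsv(p)
        header = p.read_text().splitlines()[0].split("\t")
        assert header[0] == "iteration" and header[-1] == "loglik"
        assert set(header[1:-1]) == {"mig", "tauR", "thetaA", "thetaR"}
        import json
        doc = json.loads(summarize(tr).to_json(tmp_path / "summary.json"))
        assert set(doc) == {"mig", "tauR", "thetaA", "thetaR"}
        assert {"mean", "hpd_lo", "hpd_hi", "ess"} <= set(doc["tauR"])

    def test_too_few_samples_refused(self):
        import pandas as pd
        tr = McmcTrace(samples=pd.DataFrame({"thetaA": [1.0] * 10,
                                             "loglik": [0.0] * 10}),
                       family="none", priors=PriorSpec.default("none"),
                       seed=0, acceptance={}, step_sizes={}, thin=1)
        with pytest.raises(ModelError):
            summarize(tr, level=0.95)
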