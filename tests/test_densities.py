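"""Coalescence-time densities: normalization, structural limits, and the
closed-form vs Markov-chain equivalence."""

import numpy as np
import pytest

from mscflow import (TwoSpeciesModelSpec, coal_density_two_species,
                     four_species_model, pairwise_coal_density_ctmc)
from mscflow.models import ModelError
from tests.conftest import random_valid_spec

GRID = np.linspace(0.0, 0.03, 1200)


def iso(tauR=0.004, theta=0.002):
    return TwoSpeciesModelSpec(family="none", tauR=tauR, thetaA=theta,
                               thetaR=theta)


class TestClosedForms:
    def test_normalization_across_random_specs(self, rng):
        for _ in range(25):
            dens = coal_density_two_species(random_valid_spec(rng))
            assert dens.total_mass() == pytest.approx(1.0, abs=1e-8)
            assert np.all(dens.pdf(GRID) >= -1e-12)

    def test_epochs_tile_time_axis(self, msci_base):
        dens = coal_density_two_species(msci_base)
        assert dens.epochs[0].start == 0.0
        assert np.isinf(dens.epochs[-1].end)
        for a, b in zip(dens.epochs, dens.epochs[1:]):
            assert a.end == b.start

    def test_msci_pre_divergence_mass(self, msci_base):
        # phi * (1 - exp(-2(tauR-tauX)/thetaA)): the probability that the
        # pulse moves the B lineage and it coalesces before the root
        dens = coal_density_two_species(msci_base)
        assert float(dens.cdf(0.004 - 1e-15)[0]) == pytest.approx(0.17293,
                                                                  abs=5e-5)
        assert np.all(dens.pdf(np.linspace(0, 0.002, 50, endpoint=False)) == 0)

    def test_isolation_limits(self):
        base = coal_density_two_species(iso())
        msci0 = coal_density_two_species(TwoSpeciesModelSpec(
            family="MSCI", phi=0.0, tauX=0.002, tauR=0.004, thetaA=0.002,
            thetaR=0.002))
        im0 = coal_density_two_species(TwoSpeciesModelSpec(
            family="IM", w=0.0, tauR=0.004, thetaA=0.002, thetaR=0.002))
        for other in (msci0, im0):
            assert np.abs(other.pdf(GRID) - base.pdf(GRID)).max() < 1e-12

    def test_iim_and_sc_collapse_to_im(self):
        im = coal_density_two_species(TwoSpeciesModelSpec(
            family="IM", w=120.0, tauR=0.004, thetaA=0.002, thetaR=0.002))
        iim = coal_density_two_species(TwoSpeciesModelSpec(
            family="IIM", w=120.0, tauT=1e-12, tauR=0.004, thetaA=0.002,
            thetaR=0.002))
        sc = coal_density_two_species(TwoSpeciesModelSpec(
            family="SC", w=120.0, tauT=0.004 - 1e-12, tauR=0.004,
            thetaA=0.002, thetaR=0.002))
        assert np.abs(iim.pdf(GRID) - im.pdf(GRID)).max() < 1e-6
        assert np.abs(sc.pdf(GRID) - im.pdf(GRID)).max() < 1e-6

    def test_equal_rate_convolution_is_continuous(self):
        # w == 2/thetaA triggers the degenerate t*exp(-rt) segment
        spec = TwoSpeciesModelSpec(family="IM", w=1000.0, tauR=0.004,
                                   thetaA=0.002, thetaR=0.002)
        dens = coal_density_two_species(spec)
        assert dens.total_mass() == pytest.approx(1.0, abs=1e-8)
        near = TwoSpeciesModelSpec(family="IM", w=1000.5, tauR=0.004,
                                   thetaA=0.002, thetaR=0.002)
        diff = np.abs(dens.pdf(GRID)
                      - coal_density_two_species(near).pdf(GRID)).max()
        assert diff < 0.5  # densities of order 1e2: continuity in w

    def test_mean_and_quantile_consistency(self, msci_base):
        dens = coal_density_two_species(msci_base)
        q = dens.quantile(0.5)
        assert float(dens.cdf(q)[0]) == pytest.approx(0.5, abs=1e-9)
        # independent route to E[t]: the Poisson mixture gives E[x] = 2n E[t]
        from mscflow import diff_count_pmf
        n = 4000
        xs = np.arange(n + 1)
        mean_x = float((xs * diff_count_pmf(xs, n, msci_base)).sum())
        assert dens.mean() == pytest.approx(mean_x / (2 * n), rel=1e-8)


class TestCtmcEquivalence:
    @pytest.mark.parametrize("family,kw", [
        ("MSCI", dict(phi=0.2, tauX=0.002)),
        ("IM", dict(w=80.0)),
        ("IIM", dict(w=130.0, tauT=0.0015)),
        ("SC", dict(w=80.0, tauT=0.002)),
        ("none", dict()),
    ])
    def test_closed_form_matches_markov_chain(self, family, kw):
        spec = TwoSpeciesModelSpec(family=family, tauR=0.004, thetaA=0.002,
                                   thetaR=0.002, **kw)
        closed = coal_density_two_species(spec)
        ctmc = pairwise_coal_density_ctmc(spec.to_gene_flow_model(0.01),
                                          "A", "B")
        assert np.abs(closed.pdf(GRID) - ctmc.pdf(GRID)).max() < 1e-6

    @pytest.mark.parametrize("which,direction", [
        ("A", "I"), ("B", "I"), ("C", "I"), ("C", "B"), ("D", "O")])
    def test_four_species_densities_normalize(self, which, direction):
        model = four_species_model(which, direction)
        dens = pairwise_coal_density_ctmc(model, "A", "B")
        assert dens.total_mass() == pytest.approx(1.0, abs=1e-8)
        assert np.all(dens.pdf(GRID) >= -1e-9)

    def test_no_gene_flow_density_zero_before_mrca(self):
        model = four_species_model("C", "I")
        # strip the band: A and B first meet in S at tauS = 0.006
        from mscflow import GeneFlowModel
        bare = GeneFlowModel(model.tree, "none")
        dens = pairwise_coal_density_ctmc(bare, "A", "B")
        early = np.linspace(0, 0.006, 200, endpoint=False)
        assert np.all(dens.pdf(early) == 0.0)

    def test_origins_must_exist_at_sampling_time(self):
        model = four_species_model("C", "I")
        with pytest.raises(ModelError):
            pairwise_coal_density_ctmc(model, "A", "T")


class TestExport:
    def test_tsv_export_shape(self, msci_base):
        dens = coal_density_two_species(msci_base)
        text = dens.to_tsv(np.linspace(0, 0.01, 11))
        lines = text.strip().split("\n")
        assert lines[0] == "t\tdensity"
        assert len(lines) == 12
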