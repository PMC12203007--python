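"""Domain-type invariants, the pulse/continuous conversions, and model IO."""

import io
import math

import pytest
from hypothesis import given, settings, strategies as st

from mscflow import (GeneFlowModel, IntrogressionEvent, MigrationBand,
                     M0_from_phi, SpeciesTree, TwoSpeciesModelSpec,
                     four_species_model, load_model_yaml, phi0_from_M,
                     two_species_model)
from mscflow.models import ModelError, dump_model_yaml


@pytest.fixture(scope="module")
def two_tip_tree() -> SpeciesTree:
    return SpeciesTree(parent={"A": "R", "B": "R", "R": None},
                       tau={"A": 0.0, "B": 0.0, "R": 0.004},
                       theta={"A": 0.002, "B": 0.01, "R": 0.002})


class TestSpeciesTree:
    def test_basic_structure(self, two_tip_tree):
        assert two_tip_tree.root == "R"
        assert two_tip_tree.tips == ["A", "B"]
        assert two_tip_tree.span("A") == (0.0, 0.004)
        assert two_tip_tree.span("R") == (0.004, math.inf)
        assert two_tip_tree.mrca("A", "B") == "R"
        assert two_tip_tree.alive_at(0.001) == ["A", "B"]
        assert two_tip_tree.ancestor_at("A", 0.01) == "R"

    @pytest.mark.parametrize("bad", [
        dict(theta={"A": -0.002, "B": 0.01, "R": 0.002}),   # negative theta
        dict(tau={"A": 0.0, "B": 0.0, "R": 0.0}),           # child age >= parent
        dict(parent={"A": None, "B": None, "R": None}),     # multiple roots
    ])
    def test_invalid_trees_rejected(self, bad):
        base = dict(parent={"A": "R", "B": "R", "R": None},
                    tau={"A": 0.0, "B": 0.0, "R": 0.004},
                    theta={"A": 0.002, "B": 0.01, "R": 0.002})
        base.update(bad)
        with pytest.raises(ModelError):
            SpeciesTree(**base)


class TestGeneFlowDecorations:
    def test_event_must_fall_inside_both_branches(self, two_tip_tree):
        with pytest.raises(ModelError):
            GeneFlowModel(two_tip_tree, "MSC-I", events=(
                IntrogressionEvent("A", "B", 0.005, 0.2),))

    def test_band_may_not_outlive_the_merge(self, two_tip_tree):
        with pytest.raises(ModelError):
            GeneFlowModel(two_tip_tree, "MSC-M", bands=(
                MigrationBand("A", "B", 0.2, 0.0, 0.005),))

    def test_modes_are_exclusive(self, two_tip_tree):
        ev = IntrogressionEvent("A", "B", 0.002, 0.2)
        with pytest.raises(ModelError):
            GeneFlowModel(two_tip_tree, "MSC-M", events=(ev,))
        with pytest.raises(ModelError):
            GeneFlowModel(two_tip_tree, "none", events=(ev,))

    def test_backward_rate_is_4M_over_theta_dest(self, two_tip_tree):
        band = MigrationBand("A", "B", 0.2, 0.0, 0.004)
        assert band.backward_rate(two_tip_tree) == pytest.approx(80.0)


class TestTwoSpeciesSpec:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ModelError):
            TwoSpeciesModelSpec(family="MSCI", phi=1.2, tauX=0.002,
                                tauR=0.004, thetaA=0.002, thetaR=0.002)
        with pytest.raises(ModelError):
            TwoSpeciesModelSpec(family="IIM", w=10.0, tauT=0.005,
                                tauR=0.004, thetaA=0.002, thetaR=0.002)

    def test_free_params_reflect_identifiability(self):
        iim = TwoSpeciesModelSpec(family="IIM", w=10.0, tauT=0.002,
                                  tauR=0.004, thetaA=0.002, thetaR=0.002)
        # thetaB/thetaT never appear: migration enters via w = 4M/theta only
        assert iim.free_params() == ["w", "tauT", "tauR", "thetaA", "thetaR"]

    def test_equivalent_gene_flow_model(self, msci_base):
        gfm = msci_base.to_gene_flow_model(thetaB=0.01)
        assert gfm.mode == "MSC-I"
        (ev,) = gfm.events
        assert (ev.source, ev.dest, ev.tau, ev.phi) == ("A", "B", 0.002, 0.2)


class TestConversions:
    def test_round_trip_identity(self):
        m0 = M0_from_phi(0.2, 0.01, 0.002)
        assert m0 == pytest.approx(0.2789, abs=5e-5)  # direct evaluation
        assert phi0_from_M(m0, 0.01, 0.002) == pytest.approx(0.2, abs=1e-12)

    def test_limits(self):
        assert phi0_from_M(0.0, 0.01, 0.002) == 0.0
        assert phi0_from_M(5.0, 0.01, 1e4) == pytest.approx(1.0)
        assert M0_from_phi(0.0, 0.01, 0.002) == 0.0
        with pytest.raises(ModelError):
            M0_from_phi(1.0, 0.01, 0.002)

    @given(M=st.floats(1e-3, 1.0), dtau=st.floats(1e-4, 0.01),
           thetaB=st.floats(5e-3, 0.05), phi=st.floats(1e-6, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_conversions_strictly_increasing(self, M, dtau, thetaB, phi):
        # regime chosen below saturation (phi0 < 1 in double precision)
        base = phi0_from_M(M, thetaB, dtau)
        assert phi0_from_M(M * 1.01, thetaB, dtau) > base
        assert phi0_from_M(M, thetaB, dtau * 1.01) > base
        assert M0_from_phi(phi * 1.001, thetaB, dtau) > \
            M0_from_phi(phi, thetaB, dtau)


class TestStudyModels:
    def test_base_two_species_model_matches_legend(self, msci_base_model):
        tree = msci_base_model.tree
        assert tree.theta == {"A": 0.002, "B": 0.01, "R": 0.002}
        assert tree.tau["R"] == pytest.approx(0.004)
        (ev,) = msci_base_model.events
        assert ev.tau == pytest.approx(0.002)

    @pytest.mark.parametrize("which,tauT,pair,window", [
        ("C", 0.004, ("A", "B"), (0.0, 0.004)),
        ("D", 0.002, ("A", "T"), (0.002, 0.006)),
    ])
    def test_migration_models(self, which, tauT, pair, window):
        m = four_species_model(which)
        assert m.tree.tau["T"] == pytest.approx(tauT)
        (band,) = m.bands
        assert (band.source, band.dest) == pair
        assert (band.t_start, band.t_end) == pytest.approx(window)
        assert band.M == pytest.approx(0.2)

    def test_bidirectional_band_is_two_independent_bands(self):
        m = four_species_model("C", "B")
        assert {(b.source, b.dest) for b in m.bands} == {("A", "B"), ("B", "A")}

    def test_introgression_models(self):
        a = four_species_model("A")
        b = four_species_model("B")
        assert a.events[0].dest == "B" and a.events[0].tau == pytest.approx(0.003)
        # in model B the pulse lands on the ancestor of the sister pair
        assert b.events[0].dest == "T" and b.tree.tau["T"] == pytest.approx(0.002)


class TestYamlIO:
    def test_round_trip(self, msci_base_model):
        text = dump_model_yaml(msci_base_model)
        back = load_model_yaml(io.StringIO(text))
        assert back.tree.tau == pytest.approx(msci_base_model.tree.tau)
        assert back.tree.theta == pytest.approx(msci_base_model.tree.theta)
        assert back.events == msci_base_model.events

    def test_band_model_round_trip(self):
        m = four_species_model("D", "B")
        back = load_model_yaml(io.StringIO(dump_model_yaml(m)))
        assert back.bands == m.bands
        assert back.mode == "MSC-M"
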