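"""Species trees with gene flow: the domain model.

Everything here is on the mutational time scale: population sizes are
``theta = 4*N*mu`` and node ages are ``tau = T*mu`` (expected substitutions
per site).  A pair of lineages co-located in a population of size ``theta``
coalesces at rate ``2/theta``; a lineage in the destination of a migration
band with rate ``M`` (migrants per generation) jumps backward in time to the
source at rate ``4*M/theta_dest``.

Gene-flow parameters follow the real-world (forward-time) convention: an
``A -> B`` event moves individuals from A into B going forward, which means
sampled lineages currently in B move to A when the genealogy is traced
backward.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, replace

import dendropy
import yaml

__all__ = [
    "SpeciesTree",
    "IntrogressionEvent",
    "MigrationBand",
    "GeneFlowModel",
    "TwoSpeciesModelSpec",
    "phi0_from_M",
    "M0_from_phi",
    "load_model_yaml",
    "two_species_model",
    "four_species_model",
]


class ModelError(ValueError):
    """Raised when a model specification violates its invariants."""


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesTree:
    """Ultrametric species tree with per-branch theta and per-node tau.

    Parameters
    ----------
    parent : dict
        Maps each node label to its parent label; the root maps to ``None``.
    tau : dict
        Node ages in expected substitutions per site.  Tips have age 0.
    theta : dict
        Mutation-scaled population size of the branch *above* each node
        (the root's theta is the ancestral population extending to infinity).
    """

    parent: dict[str, str | None]
    tau: dict[str, float]
    theta: dict[str, float]

    def __post_init__(self) -> None:
        labels = set(self.parent)
        if set(self.tau) != labels or set(self.theta) != labels:
            raise ModelError("parent/tau/theta must share one label set")
        roots = [v for v, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ModelError(f"tree must have exactly one root, got {roots}")
        for v, p in self.parent.items():
            if p is not None and p not in labels:
                raise ModelError(f"unknown parent {p!r} of {v!r}")
            if p is not None and not self.tau[v] < self.tau[p]:
                raise ModelError(f"node {v!r} age must be < parent {p!r} age")
        for v in labels:
            if self.theta[v] <= 0:
                raise ModelError(f"theta[{v!r}] must be > 0")
            if self.tau[v] < 0:
                raise ModelError(f"tau[{v!r}] must be >= 0")
        for t in self.tips:
            if self.tau[t] != 0.0:
                raise ModelError(f"tip {t!r} must have age 0")

    @property
    def root(self) -> str:
        return next(v for v, p in self.parent.items() if p is None)

    @property
    def tips(self) -> list[str]:
        kids = set(self.parent.values())
        return sorted(v for v in self.parent if v not in kids)

    def children(self, label: str) -> list[str]:
        return sorted(v for v, p in self.parent.items() if p == label)

    def span(self, label: str) -> tuple[float, float]:
        """Time interval [start, end) during which population `label` exists."""
        p = self.parent[label]
        end = math.inf if p is None else self.tau[p]
        return self.tau[label], end

    def alive_at(self, t: float) -> list[str]:
        return sorted(v for v in self.parent
                      if self.span(v)[0] <= t < self.span(v)[1])

    def mrca(self, a: str, b: str) -> str:
        anc_a = []
        v: str | None = a
        while v is not None:
            anc_a.append(v)
            v = self.parent[v]
        v = b
        while v not in anc_a:
            v = self.parent[v]
            assert v is not None
        return v

    def ancestor_at(self, label: str, t: float) -> str:
        """Population containing the lineage of `label` at time t."""
        v = label
        while self.span(v)[1] <= t:
            v = self.parent[v]
            assert v is not None
        return v


# ---------------------------------------------------------------------------
# Gene-flow decorations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntrogressionEvent:
    """Pulse gene flow: at time `tau`, a fraction `phi` of the (forward-time)
    destination population is replaced by migrants from the source."""

    source: str
    dest: str
    tau: float
    phi: float

    def validate(self, tree: SpeciesTree) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ModelError("phi must lie in [0, 1]")
        mrca_age = tree.tau[tree.mrca(self.source, self.dest)]
        if not 0.0 < self.tau < mrca_age:
            raise ModelError(
                f"introgression time {self.tau} must lie in (0, mrca age {mrca_age})")
        for lbl in (self.source, self.dest):
            s, e = tree.span(lbl)
            if not (s <= self.tau < e):
                raise ModelError(
                    f"population {lbl!r} does not exist at time {self.tau}")


@dataclass(frozen=True)
class MigrationBand:
    """Continuous gene flow from `source` to `dest` (forward time) over
    [t_start, t_end) at rate `M` migrants per generation (M = N_dest * m)."""

    source: str
    dest: str
    M: float
    t_start: float
    t_end: float

    def validate(self, tree: SpeciesTree) -> None:
        if self.M < 0:
            raise ModelError("migration rate M must be >= 0")
        if not (0.0 <= self.t_start < self.t_end):
            raise ModelError("need 0 <= t_start < t_end")
        merge = tree.tau[tree.mrca(self.source, self.dest)]
        if self.t_end > merge + 1e-15:
            raise ModelError("band must end no later than the populations merge")
        for lbl in (self.source, self.dest):
            s, e = tree.span(lbl)
            if not (s <= self.t_start and self.t_end <= e + 1e-15):
                raise ModelError(
                    f"population {lbl!r} does not span the band interval")

    def backward_rate(self, tree: SpeciesTree) -> float:
        """Per-lineage backward jump rate dest -> source, 4M/theta_dest."""
        return 4.0 * self.M / tree.theta[self.dest]


@dataclass(frozen=True)
class GeneFlowModel:
    """A species tree plus one mode of gene flow (pulse, continuous or none)."""

    tree: SpeciesTree
    mode: str = "none"  # "MSC-I" | "MSC-M" | "none"
    events: tuple[IntrogressionEvent, ...] = ()
    bands: tuple[MigrationBand, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("MSC-I", "MSC-M", "none"):
            raise ModelError(f"unknown mode {self.mode!r}")
        if self.mode == "MSC-I" and self.bands:
            raise ModelError("MSC-I models carry no migration bands")
        if self.mode == "MSC-M" and self.events:
            raise ModelError("MSC-M models carry no introgression events")
        if self.mode == "none" and (self.events or self.bands):
            raise ModelError("mode 'none' carries no gene flow")
        for ev in self.events:
            ev.validate(self.tree)
        for b in self.bands:
            b.validate(self.tree)


# ---------------------------------------------------------------------------
# Two-species parametric families (the closed-form likelihood's home)
# ---------------------------------------------------------------------------

_FAMILIES = ("MSCI", "IM", "IIM", "SC", "none")


@dataclass(frozen=True)
class TwoSpeciesModelSpec:
    """Parameter vector for the two-species gene-flow families of the
    asymptotic analysis (one sequence per species).

    Families
    --------
    MSCI : pulse ``A -> B`` at ``tauX`` with probability ``phi``; parameters
        ``{phi, tauX, tauR, thetaA, thetaB, thetaR}`` with ``thetaA = thetaX``
        and ``thetaB = thetaY`` (population sizes unchanged by the pulse).
    IM : continuous flow ``A -> B`` over the whole interval ``(0, tauR)``.
    IIM : flow only early, on ``(tauT, tauR)`` (isolation with initial
        migration; ``tauT`` is when migration *stops*, forward in time).
    SC : flow only recently, on ``(0, tauT)`` (secondary contact).
    none : complete isolation.

    With one sequence per species ``thetaB`` (and ``thetaT`` for IIM/SC)
    cannot be estimated: the likelihood depends on migration only through the
    compound intensity ``w = 4*M/theta_dest``.  The spec therefore stores
    ``w`` directly; ``M`` for reporting is ``w * thetaB_true / 4``.
    """

    family: str
    tauR: float
    thetaA: float
    thetaR: float
    phi: float = 0.0      # MSCI only
    tauX: float = 0.0     # MSCI only
    w: float = 0.0        # IM/IIM/SC: 4M/theta_dest
    tauT: float = 0.0     # IIM/SC only
    equal_theta: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ModelError(f"unknown family {self.family!r}")
        if self.tauR <= 0 or self.thetaA <= 0 or self.thetaR <= 0:
            raise ModelError("tauR, thetaA, thetaR must be > 0")
        if self.equal_theta and not math.isclose(self.thetaA, self.thetaR,
                                                 rel_tol=0, abs_tol=0):
            raise ModelError("equal_theta spec requires thetaA == thetaR")
        if self.family == "MSCI":
            if not 0.0 <= self.phi <= 1.0:
                raise ModelError("phi must lie in [0, 1]")
            if not 0.0 < self.tauX < self.tauR:
                raise ModelError("need 0 < tauX < tauR")
        elif self.family in ("IM", "IIM", "SC"):
            if self.w < 0:
                raise ModelError("migration intensity w must be >= 0")
            if self.family in ("IIM", "SC") and not 0.0 < self.tauT < self.tauR:
                raise ModelError("need 0 < tauT < tauR")

    def free_params(self) -> list[str]:
        """Names of the free parameters entering the S=1 likelihood."""
        names: list[str]
        if self.family == "MSCI":
            names = ["phi", "tauX", "tauR", "thetaA", "thetaR"]
        elif self.family == "IM":
            names = ["w", "tauR", "thetaA", "thetaR"]
        elif self.family in ("IIM", "SC"):
            names = ["w", "tauT", "tauR", "thetaA", "thetaR"]
        else:
            names = ["tauR", "thetaA", "thetaR"]
        if self.equal_theta:
            names.remove("thetaR")
        return names

    def with_params(self, **kw: float) -> "TwoSpeciesModelSpec":
        if self.equal_theta and "thetaA" in kw:
            kw.setdefault("thetaR", kw["thetaA"])
        return replace(self, **kw)

    def to_gene_flow_model(self, thetaB: float = 1.0) -> GeneFlowModel:
        """Equivalent :class:`GeneFlowModel` on the tree ``(A,B)R``.

        ``thetaB`` does not affect the between-species coalescence density
        provided the band's migrant rate is chosen so the backward jump rate
        matches ``w``; it is exposed so simulated within-B coalescence is
        meaningful when sampling more than one sequence.
        """
        tree = SpeciesTree(
            parent={"A": "R", "B": "R", "R": None},
            tau={"A": 0.0, "B": 0.0, "R": self.tauR},
            theta={"A": self.thetaA, "B": thetaB, "R": self.thetaR},
        )
        if self.family == "MSCI":
            return GeneFlowModel(tree, "MSC-I", events=(
                IntrogressionEvent("A", "B", self.tauX, self.phi),))
        if self.family in ("IM", "IIM", "SC") and self.w > 0:
            M = self.w * thetaB / 4.0
            if self.family == "IM":
                t0, t1 = 0.0, self.tauR
            elif self.family == "IIM":
                t0, t1 = self.tauT, self.tauR
            else:  # SC
                t0, t1 = 0.0, self.tauT
            return GeneFlowModel(tree, "MSC-M", bands=(
                MigrationBand("A", "B", M, t0, t1),))
        return GeneFlowModel(tree, "none")


# ---------------------------------------------------------------------------
# Pulse <-> continuous conversions (total amount of gene flow)
# ---------------------------------------------------------------------------

def phi0_from_M(M: float, thetaB: float, dtau: float) -> float:
    """Probability that a destination lineage traces back to the source under
    continuous migration at rate ``M`` over a period ``dtau``.

    ``phi0 = 1 - exp(-(4M/thetaB) * dtau)``: the CDF of the exponential
    waiting time until a backward migration jump.
    """
    if M < 0 or thetaB <= 0 or dtau < 0:
        raise ModelError("need M >= 0, thetaB > 0, dtau >= 0")
    return -math.expm1(-4.0 * M * dtau / thetaB)


def M0_from_phi(phi: float, thetaB: float, dtau: float) -> float:
    """Continuous-migration rate whose total gene flow over ``dtau`` equals
    a pulse of probability ``phi``: ``M0 = thetaB/(4 dtau) * log(1/(1-phi))``."""
    if not 0.0 <= phi < 1.0:
        raise ModelError("phi must lie in [0, 1)")
    if thetaB <= 0 or dtau <= 0:
        raise ModelError("need thetaB > 0, dtau > 0")
    return thetaB / (4.0 * dtau) * (-math.log1p(-phi))


# ---------------------------------------------------------------------------
# Ready-made study models
# ---------------------------------------------------------------------------

def two_species_model(phi: float = 0.2, theta0: float = 0.002,
                      theta1: float = 0.01) -> GeneFlowModel:
    """The two-species MSC-I data-generating model: thin branches (A, X, R)
    of size ``theta0``, thick branches (B, Y) of size ``theta1 = 5*theta0``,
    introgression A -> B at ``tauX = theta0`` after divergence at
    ``tauR = 2*theta0``."""
    tree = SpeciesTree(
        parent={"A": "R", "B": "R", "R": None},
        tau={"A": 0.0, "B": 0.0, "R": 2.0 * theta0},
        theta={"A": theta0, "B": theta1, "R": theta0},
    )
    return GeneFlowModel(tree, "MSC-I", events=(
        IntrogressionEvent("A", "B", theta0, phi),))


def two_species_mscispec(phi: float = 0.2, theta0: float = 0.002) -> TwoSpeciesModelSpec:
    """`two_species_model` as a TwoSpeciesModelSpec (S=1 parameterization)."""
    return TwoSpeciesModelSpec(family="MSCI", phi=phi, tauX=theta0,
                               tauR=2.0 * theta0, thetaA=theta0, thetaR=theta0)


def _four_species_tree(tauT: float, theta0: float) -> SpeciesTree:
    # topology ((A, (B, C)T)S, D)R with tauR = 4*theta0, tauS = 3*theta0
    return SpeciesTree(
        parent={"A": "S", "B": "T", "C": "T", "T": "S", "S": "R",
                "D": "R", "R": None},
        tau={"A": 0.0, "B": 0.0, "C": 0.0, "D": 0.0,
             "T": tauT, "S": 3.0 * theta0, "R": 4.0 * theta0},
        theta={v: theta0 for v in ("A", "B", "C", "D", "T", "S", "R")},
    )


def four_species_model(which: str, direction: str = "I", *,
                       theta0: float = 0.002, phi: float = 0.2,
                       M: float = 0.2) -> GeneFlowModel:
    """The four-species simulation models on the tree ((A,(B,C))S, D)R.

    Parameters
    ----------
    which : {"A", "B", "C", "D"}
        A/B are pulse-introgression (MSC-I) models, C/D continuous-migration
        (MSC-M) models.  A and C place gene flow between the nonsister pair
        A-B; B and D place it between the sister pair A-T (T = ancestor of
        B and C).
    direction : {"I", "O", "B"}
        For the MSC-M models only: inflow (A->B), outflow (B->A) or
        bidirectional.  A bidirectional band is two independent bands.
    """
    if which in ("A", "B"):
        tauT = (2.0 if which == "A" else 1.0) * theta0
        tree = _four_species_tree(tauT, theta0)
        tauX = 1.5 * theta0
        dest = "B" if which == "A" else "T"
        return GeneFlowModel(tree, "MSC-I", events=(
            IntrogressionEvent("A", dest, tauX, phi),))
    if which in ("C", "D"):
        tauT = (2.0 if which == "C" else 1.0) * theta0
        tree = _four_species_tree(tauT, theta0)
        if which == "C":
            pair, t0, t1 = ("A", "B"), 0.0, tauT
        else:
            pair, t0, t1 = ("A", "T"), tauT, 3.0 * theta0
        bands = []
        if direction in ("I", "B"):
            bands.append(MigrationBand(pair[0], pair[1], M, t0, t1))
        if direction in ("O", "B"):
            bands.append(MigrationBand(pair[1], pair[0], M, t0, t1))
        if direction not in ("I", "O", "B"):
            raise ModelError(f"unknown direction {direction!r}")
        return GeneFlowModel(tree, "MSC-M", bands=tuple(bands))
    raise ModelError(f"unknown four-species model {which!r}")


# ---------------------------------------------------------------------------
# YAML model files
# ---------------------------------------------------------------------------

def _tree_from_newick(newick: str, thetas: dict[str, float]) -> SpeciesTree:
    dtree = dendropy.Tree.get(data=newick, schema="newick",
                              suppress_internal_node_taxa=False)
    parent: dict[str, str | None] = {}
    tau: dict[str, float] = {}

    def label_of(node) -> str:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        if node.label:
            return node.label
        raise ModelError("every node in the model tree must be labeled")

    dtree.calc_node_ages(ultrametricity_precision=1e-10)
    for node in dtree.preorder_node_iter():
        lbl = label_of(node)
        parent[lbl] = None if node.parent_node is None else label_of(node.parent_node)
        tau[lbl] = float(node.age)
    missing = set(parent) - set(thetas)
    if missing:
        raise ModelError(f"missing theta for nodes: {sorted(missing)}")
    return SpeciesTree(parent=parent, tau=tau,
                       theta={k: float(thetas[k]) for k in parent})


def load_model_yaml(source) -> GeneFlowModel:
    """Read a gene-flow model from YAML.

    Expected blocks: ``tree`` (Newick, labeled nodes, branch lengths on the
    mutational scale), ``thetas`` (label -> theta), and optionally ``events``
    (MSC-I pulses: source, dest, tau, phi) or ``bands`` (MSC-M: source, dest,
    M, t_start, t_end).
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    tree = _tree_from_newick(doc["tree"], doc["thetas"])
    events = tuple(IntrogressionEvent(e["source"], e["dest"],
                                      float(e["tau"]), float(e["phi"]))
                   for e in doc.get("events", []) or [])
    bands = tuple(MigrationBand(b["source"], b["dest"], float(b["M"]),
                                float(b["t_start"]), float(b["t_end"]))
                  for b in doc.get("bands", []) or [])
    if events and bands:
        raise ModelError("a model may use pulses or bands, not both")
    mode = "MSC-I" if events else ("MSC-M" if bands else "none")
    return GeneFlowModel(tree, mode, events=events, bands=bands)


def dump_model_yaml(model: GeneFlowModel) -> str:
    """Serialize a model back to the YAML dialect read by `load_model_yaml`."""
    tree = model.tree

    def nwk(label: str) -> str:
        kids = tree.children(label)
        s, e = tree.span(label)
        blen = "" if math.isinf(e) else f":{e - s:.10g}"
        if not kids:
            return f"{label}{blen}"
        return "(" + ",".join(nwk(k) for k in kids) + f"){label}{blen}"

    doc: dict = {
        "tree": nwk(tree.root) + ";",
        "thetas": {k: float(v) for k, v in sorted(tree.theta.items())},
    }
    if model.events:
        doc["events"] = [dict(source=e.source, dest=e.dest, tau=e.tau, phi=e.phi)
                         for e in model.events]
    if model.bands:
        doc["bands"] = [dict(source=b.source, dest=b.dest, M=b.M,
                             t_start=b.t_start, t_end=b.t_end)
                        for b in model.bands]
    buf = _io.StringIO()
    yaml.safe_dump(doc, buf, sort_keys=False)
    return buf.getvalue()
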