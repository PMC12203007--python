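"""Structured-coalescent simulation under gene-flow models.

Backward-in-time, event-driven (exact Gillespie scheduling, no time
discretization).  Within each epoch the rates are constant: every co-located
pair of lineages coalesces at rate ``2/theta`` of its population, and every
lineage sitting in the destination of an active migration band jumps to the
band's source at rate ``4M/theta_dest``.  Introgression pulses act
instantaneously at their time point: each lineage in the destination moves
to the source independently with probability ``phi``.  At speciation nodes
populations merge into their parent.

Sequence data are evolved along the simulated genealogies under JC69, or
reduced directly to infinite-sites difference counts ``x ~ Poisson(2nt)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import DiffCountDataset, GeneTree, GeneTreeNode, LocusAlignment
from .models import GeneFlowModel, ModelError, TwoSpeciesModelSpec

__all__ = ["SimulationConfig", "sample_gene_tree", "sample_pairwise_times",
           "evolve_jc69", "simulate_diff_counts", "simulate_loci"]


@dataclass(frozen=True)
class SimulationConfig:
    """A fully seeded simulation design."""

    model: GeneFlowModel
    loci: int
    samples_per_species: int | dict[str, int]
    sites: int
    mode: str = "jc69"  # "jc69" | "infsites"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loci < 1 or self.sites < 1:
            raise ModelError("loci and sites must be >= 1")
        if self.mode not in ("jc69", "infsites"):
            raise ModelError(f"unknown mutation mode {self.mode!r}")

    def samples(self) -> dict[str, int]:
        tips = self.model.tree.tips
        if isinstance(self.samples_per_species, dict):
            return dict(self.samples_per_species)
        return {sp: int(self.samples_per_species) for sp in tips}


def _locus_rng(master_seed: int, locus: int) -> np.random.Generator:
    """Independent per-locus substream: changing L leaves earlier loci
    untouched (counter-based spawning off the master seed)."""
    return np.random.default_rng(np.random.SeedSequence(master_seed).spawn(
        locus + 1)[locus])


def sample_gene_tree(model: GeneFlowModel, samples: dict[str, int],
                     rng: np.random.Generator) -> GeneTree:
    """Simulate one genealogy for `samples` sequences per population."""
    tree = model.tree
    if not samples or any(k not in tree.parent for k in samples):
        raise ModelError("samples must name populations of the model")
    if any(v < 0 for v in samples.values()) or sum(samples.values()) < 1:
        raise ModelError("need at least one sampled sequence")

    # active lineages: (node, current population)
    lineages: list[list] = []
    for sp, k in sorted(samples.items()):
        for i in range(1, k + 1):
            node = GeneTreeNode(time=tree.tau[sp], label=f"{sp.lower()}{i}^{sp}",
                                species=sp)
            lineages.append([node, sp])

    pts = sorted({0.0} | {tree.tau[v] for v in tree.parent}
                 | {b.t_start for b in model.bands}
                 | {b.t_end for b in model.bands}
                 | {e.tau for e in model.events})
    events_at: dict[float, list] = {}
    for e in model.events:
        events_at.setdefault(e.tau, []).append(e)

    migrations: list[tuple[float, str, str]] = []
    t = 0.0
    boundaries = pts[1:] + [math.inf]
    for t_end in boundaries:
        # epoch [t, t_end)
        while len(lineages) > 1:
            counts: dict[str, int] = {}
            for _, pop in lineages:
                counts[pop] = counts.get(pop, 0) + 1
            rates: list[tuple[float, str, object]] = []
            for pop, k in counts.items():
                if k >= 2:
                    rates.append((k * (k - 1) / tree.theta[pop], "coal", pop))
            for b in model.bands:
                if b.t_start <= t and b.t_end >= t_end and counts.get(b.dest, 0):
                    rates.append((counts[b.dest] * b.backward_rate(tree),
                                  "mig", b))
            total = sum(r for r, _, _ in rates)
            if total == 0.0:
                break
            dt = rng.exponential(1.0 / total)
            if t + dt >= t_end:
                break
            t += dt
            u = rng.uniform(0.0, total)
            acc = 0.0
            for r, kind, obj in rates:
                acc += r
                if u < acc:
                    break
            if kind == "coal":
                pop = obj
                members = [i for i, (_, p) in enumerate(lineages) if p == pop]
                i, j = rng.choice(members, size=2, replace=False)
                a, b_ = lineages[i][0], lineages[j][0]
                parent = GeneTreeNode(time=t, children=[a, b_])
                keep = [ln for k2, ln in enumerate(lineages) if k2 not in (i, j)]
                keep.append([parent, pop])
                lineages = keep
            else:
                band = obj
                members = [i for i, (_, p) in enumerate(lineages)
                           if p == band.dest]
                i = int(rng.choice(members))
                lineages[i][1] = band.source
                migrations.append((t, band.dest, band.source))
        if len(lineages) == 1:
            break
        # boundary actions at t_end
        t = t_end
        for ev in events_at.get(t_end, []):
            for ln in lineages:
                if ln[1] == ev.dest and rng.random() < ev.phi:
                    ln[1] = ev.source
                    migrations.append((t_end, ev.dest, ev.source))
        for v in tree.parent:
            if tree.span(v)[1] == t_end:
                parent = tree.parent[v]
                for ln in lineages:
                    if ln[1] == v:
                        ln[1] = parent
    if len(lineages) != 1:  # pragma: no cover
        raise RuntimeError("simulation ended with unmerged lineages")
    return GeneTree(root=lineages[0][0], migrations=migrations)


def sample_pairwise_times(model: GeneFlowModel, origin_a: str, origin_b: str,
                          size: int, rng: np.random.Generator) -> np.ndarray:
    """Coalescence times of one lineage from each of two populations,
    by repeated genealogy simulation (the simulation oracle for the
    analytic densities)."""
    out = np.empty(size)
    samples = {origin_a: 1, origin_b: 1}
    for i in range(size):
        out[i] = sample_gene_tree(model, samples, rng).tmrca()
    return out


# ---------------------------------------------------------------------------
# mutation models
# ---------------------------------------------------------------------------

def evolve_jc69(tree: GeneTree, n: int, rng: np.random.Generator) -> LocusAlignment:
    """Evolve a root sequence (uniform over TCAG) down the genealogy under
    Jukes-Cantor; branch lengths are expected substitutions per site."""
    if n < 1:
        raise ModelError("need n >= 1")
    root_seq = rng.integers(0, 4, size=n, dtype=np.int8)
    names: list[str] = []
    rows: list[np.ndarray] = []

    def descend(node: GeneTreeNode, seq: np.ndarray, parent_time: float) -> None:
        b = parent_time - node.time
        if b > 0.0:
            p_change = 0.75 * (1.0 - math.exp(-4.0 * b / 3.0))
            hit = rng.random(n) < p_change
            k = int(hit.sum())
            if k:
                seq = seq.copy()
                # uniform among the three other bases
                seq[hit] = (seq[hit] + rng.integers(1, 4, size=k)) % 4
        if node.is_tip():
            names.append(node.label or "?")
            rows.append(seq)
            return
        for c in node.children:
            descend(c, seq, node.time)

    descend(tree.root, root_seq, tree.root.time)
    order = np.argsort(names)
    return LocusAlignment([names[i] for i in order],
                          np.stack([rows[i] for i in order]))


# ---------------------------------------------------------------------------
# two-species shortcuts
# ---------------------------------------------------------------------------

def sample_coal_times_two_species(spec: TwoSpeciesModelSpec, size: int,
                                  rng: np.random.Generator) -> np.ndarray:
    """Vectorized exact draws of t_ab under the two-species families."""
    tauR = spec.tauR
    expA = lambda m: rng.exponential(spec.thetaA / 2.0, size=m)  # noqa: E731
    t = np.empty(size)
    if spec.family == "MSCI" and spec.phi > 0.0:
        switched = rng.random(size) < spec.phi
        tA = spec.tauX + expA(size)
        early = switched & (tA < tauR)
    elif spec.family in ("IM", "IIM", "SC") and spec.w > 0.0:
        lo = spec.tauT if spec.family == "IIM" else 0.0
        hi = spec.tauT if spec.family == "SC" else tauR
        jump = lo + rng.exponential(1.0 / spec.w, size=size)
        tA = jump + expA(size)
        early = (jump < hi) & (tA < tauR)
    else:
        early = np.zeros(size, dtype=bool)
        tA = np.empty(size)
    t[early] = tA[early]
    rest = (~early).sum()
    t[~early] = tauR + rng.exponential(spec.thetaR / 2.0, size=rest)
    return t


def simulate_diff_counts(spec: TwoSpeciesModelSpec, L: int, n: int,
                         rng: np.random.Generator) -> DiffCountDataset:
    """Infinite-sites data: per locus draw t_ab, then x ~ Poisson(2nt)
    capped at the n sites."""
    if L < 1 or n < 1:
        raise ModelError("need L, n >= 1")
    t = sample_coal_times_two_species(spec, L, rng)
    x = np.minimum(rng.poisson(2.0 * n * t), n)
    return DiffCountDataset(x, np.full(L, n))


# ---------------------------------------------------------------------------
# full multilocus simulation
# ---------------------------------------------------------------------------

def simulate_loci(config: SimulationConfig) -> list[LocusAlignment] | DiffCountDataset:
    """Simulate a multilocus dataset per `config`.

    JC69 mode returns one alignment per locus; infinite-sites mode (defined
    for two sampled sequences) returns a DiffCountDataset.  Loci use
    independent, counter-derived RNG substreams of the master seed.
    """
    samples = config.samples()
    if config.mode == "infsites":
        total = sum(samples.values())
        if total != 2:
            raise ModelError("infinite-sites difference counts are defined "
                             "for exactly two sampled sequences")
        xs = np.empty(config.loci, dtype=int)
        for locus in range(config.loci):
            rng = _locus_rng(config.seed, locus)
            t = sample_gene_tree(config.model, samples, rng).tmrca()
            xs[locus] = min(rng.poisson(2.0 * config.sites * t), config.sites)
        return DiffCountDataset(xs, np.full(config.loci, config.sites))
    out = []
    for locus in range(config.loci):
        rng = _locus_rng(config.seed, locus)
        gt = sample_gene_tree(config.model, samples, rng)
        out.append(evolve_jc69(gt, config.sites, rng))
    return out
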