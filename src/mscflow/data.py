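"""Dataset containers and plain-text readers/writers.

Multilocus data travel in two shapes: full alignments (one per locus, for
sequence simulation) and per-locus pairwise difference counts ``(x, n)``
(the sufficient data for the two-species one-sequence-per-species
likelihood).  Writers target sequential PHYLIP (one block per locus, names
tagged ``individual^species``), per-locus FASTA, a two-column species map,
and TSV difference counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = np.array(list("TCAG"))

__all__ = ["DiffCountDataset", "LocusAlignment", "GeneTreeNode", "GeneTree",
           "write_phylip", "write_fasta", "write_imap", "read_phylip",
           "write_diff_counts", "read_diff_counts", "write_gene_trees"]


@dataclass
class DiffCountDataset:
    """Per-locus pairwise difference counts: x differences out of n sites."""

    x: np.ndarray
    n: np.ndarray  # per-locus site counts (commonly constant)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=int)
        self.n = np.broadcast_to(np.asarray(self.n, dtype=int),
                                 self.x.shape).copy()
        if self.x.size < 1:
            raise ValueError("need at least one locus")
        if np.any(self.x < 0) or np.any(self.x > self.n):
            raise ValueError("need 0 <= x <= n at every locus")

    @property
    def L(self) -> int:
        return int(self.x.size)

    def __add__(self, other: "DiffCountDataset") -> "DiffCountDataset":
        return DiffCountDataset(np.concatenate([self.x, other.x]),
                                np.concatenate([self.n, other.n]))


@dataclass
class LocusAlignment:
    """Equal-length sequences over {T,C,A,G}; names carry species labels
    as ``individual^species``."""

    names: list[str]
    seqs: np.ndarray  # (num_seqs, n) of small ints indexing BASES

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs)
        if self.seqs.ndim != 2 or len(self.names) != self.seqs.shape[0]:
            raise ValueError("one name per sequence row required")

    @property
    def n_sites(self) -> int:
        return int(self.seqs.shape[1])

    def sequence(self, i: int) -> str:
        return "".join(BASES[self.seqs[i]])

    def diff_count(self, i: int, j: int) -> int:
        return int((self.seqs[i] != self.seqs[j]).sum())


@dataclass
class GeneTreeNode:
    time: float
    children: list = field(default_factory=list)
    label: str | None = None   # tips only
    species: str | None = None  # sampling population (tips only)

    def is_tip(self) -> bool:
        return not self.children


@dataclass
class GeneTree:
    """A simulated genealogy with coalescence times in mutational units and
    the lineage-movement history (migration jumps / pulse switches)."""

    root: GeneTreeNode
    migrations: list[tuple[float, str, str]] = field(default_factory=list)
    # (time, from_pop, to_pop) per recorded backward-in-time move

    def tips(self) -> list[GeneTreeNode]:
        out: list[GeneTreeNode] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            if v.is_tip():
                out.append(v)
            stack.extend(v.children)
        return sorted(out, key=lambda v: v.label or "")

    def tmrca(self) -> float:
        return self.root.time

    def newick(self, digits: int = 10) -> str:
        def rec(v: GeneTreeNode, parent_time: float) -> str:
            blen = f":{parent_time - v.time:.{digits}g}"
            if v.is_tip():
                return f"{v.label}{blen}"
            return "(" + ",".join(rec(c, v.time) for c in v.children) + f"){blen}"

        inner = "(" + ",".join(rec(c, self.root.time)
                               for c in self.root.children) + ")"
        note = ""
        if self.migrations:
            moves = "|".join(f"{t:.6g}:{a}>{b}" for t, a, b in self.migrations)
            note = f"[&migrations={moves}]"
        return inner + note + ";"


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

def write_phylip(alignments: list[LocusAlignment], path) -> None:
    """Sequential multilocus PHYLIP, one block per locus: a header line
    ``nseq nsites`` then one ``name  sequence`` line per sequence."""
    alignments = list(alignments)
    if not alignments:
        raise ValueError("no alignments to write")
    with open(path, "w") as fh:
        for aln in alignments:
            fh.write(f"{len(aln.names)} {aln.n_sites}\n")
            pad = max(len(s) for s in aln.names) + 2
            for i, name in enumerate(aln.names):
                fh.write(f"{name:<{pad}}{aln.sequence(i)}\n")
            fh.write("\n")


def read_phylip(path) -> list[LocusAlignment]:
    base_ix = {b: i for i, b in enumerate(BASES)}
    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        nseq, nsites = map(int, lines[i].split())
        names, rows = [], []
        for j in range(nseq):
            name, seq = lines[i + 1 + j].split()
            if len(seq) != nsites:
                raise ValueError(f"sequence length mismatch at {name}")
            names.append(name)
            rows.append([base_ix[b] for b in seq])
        out.append(LocusAlignment(names, np.array(rows, dtype=np.int8)))
        i += 1 + nseq
    return out


def write_fasta(alignments: list[LocusAlignment], directory,
                stem: str = "locus") -> list[Path]:
    """One FASTA per locus under `directory`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, aln in enumerate(alignments):
        recs = [SeqRecord(Seq(aln.sequence(i)), id=name, description="")
                for i, name in enumerate(aln.names)]
        p = directory / f"{stem}{k + 1}.fasta"
        SeqIO.write(recs, p, "fasta")
        paths.append(p)
    return paths


def write_imap(alignment: LocusAlignment, path) -> None:
    """Two-column individual-to-species map (the ``name^species`` tags)."""
    with open(path, "w") as fh:
        for name in alignment.names:
            ind, _, sp = name.partition("^")
            fh.write(f"{ind}\t{sp or ind}\n")


def write_diff_counts(ds: DiffCountDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tx\tn\n")
        for i, (x, n) in enumerate(zip(ds.x, ds.n), start=1):
            fh.write(f"{i}\t{x}\t{n}\n")


def read_diff_counts(path) -> DiffCountDataset:
    xs, ns = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("locus"):
            raise ValueError("expected a 'locus\\tx\\tn' header")
        for line in fh:
            _, x, n = line.split()
            xs.append(int(x))
            ns.append(int(n))
    return DiffCountDataset(np.array(xs), np.array(ns))


def write_gene_trees(trees: list[GeneTree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.newick() + "\n")
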