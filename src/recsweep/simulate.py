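"""Synthetic alignments with truth-labelled recombination events.

Sequences evolve along a user-supplied tree under the Jukes–Cantor
substitution model; recombination is then implanted by copying a region
of one extant row (the donor) over the same region of another (the
acceptor).  Because the donor's *current* row is copied, nested events
(a donor that is itself recombinant) are expressible; the generation
order is recorded in the truth record.

All randomness flows through a single integer seed, so a simulation is
reproducible bit-exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .alignment import Alignment

__all__ = [
    "TruthEvent",
    "SimTruth",
    "simulate_tree_alignment",
    "implant_recombination",
    "random_tree",
    "recombinant_triplet",
]


@dataclass
class TruthEvent:
    recombinant: str
    donor: str
    begin: int  # 0-based half-open region
    end: int
    order: int


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    events: list[TruthEvent] = field(default_factory=list)
    tree: str = ""
    seed: int | None = None

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["recombinant", "donor", "begin", "end", "order"])
            for ev in self.events:
                w.writerow([ev.recombinant, ev.donor, ev.begin, ev.end, ev.order])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SimTruth":
        truth = cls()
        with open(path) as fh:
            rd = csv.DictReader(fh, delimiter="\t")
            for row in rd:
                truth.events.append(
                    TruthEvent(
                        row["recombinant"],
                        row["donor"],
                        int(row["begin"]),
                        int(row["end"]),
                        int(row["order"]),
                    )
                )
        return truth


def _parse_tree(tree: str | dendropy.Tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick")


def simulate_tree_alignment(
    tree: str | dendropy.Tree, length: int, seed: int
) -> Alignment:
    """Evolve a gapless alignment of *length* sites along *tree* (branch
    lengths in expected substitutions/site) under Jukes–Cantor.

    Per branch of length *t* each site substitutes with probability
    ``3/4 * (1 - exp(-4t/3))``, landing uniformly on the other three
    bases.  Leaf rows appear in tree leaf order.  Deterministic in *seed*.
    """
    t = _parse_tree(tree)
    rng = np.random.default_rng(seed)
    root = t.seed_node
    seqs: dict[int, np.ndarray] = {id(root): rng.integers(0, 4, size=length, dtype=np.uint8)}
    names: list[str] = []
    rows: list[np.ndarray] = []
    for node in t.preorder_node_iter():
        if node is root:
            parent_seq = seqs[id(root)]
        else:
            bl = node.edge.length if node.edge.length is not None else 0.0
            if bl < 0:
                raise ValueError(f"negative branch length {bl} in tree")
            p_sub = 0.75 * (1.0 - np.exp(-4.0 * bl / 3.0))
            parent_seq = seqs[id(node.parent_node)].copy()
            if p_sub > 0:
                mask = rng.random(length) < p_sub
                k = int(mask.sum())
                if k:
                    parent_seq[mask] = (
                        parent_seq[mask] + rng.integers(1, 4, size=k, dtype=np.uint8)
                    ) % 4
            seqs[id(node)] = parent_seq
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else f"leaf{len(names)}"
            names.append(label.replace(" ", "_"))
            rows.append(parent_seq)
    return Alignment.from_codes(names, np.stack(rows))


def implant_recombination(
    aln: Alignment,
    donor: str,
    acceptor: str,
    region: tuple[int, int],
    truth: SimTruth | None = None,
) -> tuple[Alignment, SimTruth]:
    """Copy *donor*'s residues over *acceptor*'s in the half-open *region*.

    Returns a new alignment and the extended truth record; the inputs are
    not modified.  An empty region is a no-op.
    """
    b, e = region
    if not 0 <= b <= e <= aln.length:
        raise ValueError(f"region [{b}, {e}) outside alignment of length {aln.length}")
    di = aln.index_of(donor)
    ai = aln.index_of(acceptor)
    truth = truth if truth is not None else SimTruth()
    if b == e:
        return aln, truth
    rows = list(aln.rows)
    rows[ai] = rows[ai][:b] + rows[di][b:e] + rows[ai][e:]
    out = Alignment(list(aln.names), rows, list(aln.descriptions))
    new = SimTruth(list(truth.events), truth.tree, truth.seed)
    new.events.append(TruthEvent(acceptor, donor, b, e, len(new.events) + 1))
    return out, new


def random_tree(
    n_leaves: int, seed: int, mean_tip_depth: float = 0.12, names: list[str] | None = None
) -> str:
    """A random bifurcating tree in newick form.

    Topology by recursive random bisection; branch lengths exponential,
    scaled so the expected root-to-tip path is *mean_tip_depth*
    substitutions/site (typical pairwise divergence then sits around
    ``1.5–2 × mean_tip_depth``, the range where window statistics have
    both variation and signal).
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"s{i}" for i in range(n_leaves)]
    # expected number of edges on a root-to-tip path ~ log2(n)+1
    scale = mean_tip_depth / (np.log2(max(n_leaves, 2)) + 1.0)

    def build(leaves: list[str]) -> str:
        if len(leaves) == 1:
            return f"{leaves[0]}:{rng.exponential(scale):.6f}"
        k = int(rng.integers(1, len(leaves)))
        left, right = leaves[:k], leaves[k:]
        bl = rng.exponential(scale)
        return f"({build(left)},{build(right)}):{bl:.6f}"

    order = list(rng.permutation(names))
    k = int(rng.integers(1, len(order))) if len(order) > 2 else 1
    return f"({build(order[:k])},{build(order[k:])});"


def simulate_events_dataset(
    n_leaves: int,
    length: int,
    regions: list[tuple[int, int]],
    seed: int,
    mean_tip_depth: float = 0.12,
) -> tuple[Alignment, SimTruth]:
    """A random-tree alignment with one implanted event per region.

    Acceptors are distinct sequences; each donor is the sequence most
    divergent from its acceptor among those not yet used as acceptor or
    donor — recombination between distant lineages, the regime the
    triplet scanners are designed for.  Needs ``2*len(regions)`` <=
    *n_leaves*.
    """
    if 2 * len(regions) > n_leaves:
        raise ValueError("need at least 2 sequences per event")
    tree = random_tree(n_leaves, seed, mean_tip_depth)
    aln = simulate_tree_alignment(tree, length, seed)
    truth = SimTruth(tree=tree, seed=seed)
    codes = aln.codes
    n = aln.n_sequences
    diff = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff[i, j] = diff[j, i] = np.count_nonzero(codes[i] != codes[j])
    used: set[int] = set()
    for region in regions:
        acceptor = min(set(range(n)) - used)
        used.add(acceptor)
        candidates = [k for k in range(n) if k not in used]
        donor = max(candidates, key=lambda k: diff[acceptor, k])
        used.add(donor)
        aln, truth = implant_recombination(
            aln, aln.names[donor], aln.names[acceptor], region, truth)
    return aln, truth


def recombinant_triplet(
    seed: int,
    length: int = 1000,
    parent_distance: float = 0.2,
    offshoot: float = 0.04,
    region: tuple[int, int] = (300, 700),
) -> tuple[Alignment, SimTruth]:
    """Benchmark scenario: recombinant ``C`` descends from parent ``A``
    (at JC distance *offshoot*) and carries *region* from parent ``B``;
    the parents sit at JC distance *parent_distance* from each other.
    """
    half = offshoot / 2.0
    inner = parent_distance / 2.0 - half
    if inner < 0:
        raise ValueError("offshoot larger than parent distance")
    tree = f"((A:{half:.6f},C:{half:.6f}):{inner:.6f},B:{parent_distance / 2.0:.6f});"
    aln = simulate_tree_alignment(tree, length, seed)
    truth = SimTruth(tree=tree, seed=seed)
    return implant_recombination(aln, "B", "C", region, truth)
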