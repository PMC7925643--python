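"""Repeated random haplotype sampling (RRHS) phylogenomics.

Heterozygous diploid genotypes carry no phase, so each replicate resolves
every het site independently to ref or alt with probability 1/2, yielding a
pseudo-haploid matrix; a neighbor-joining tree is built on p-distances per
replicate; the replicates are summarised in a majority-rule consensus whose
internal branches carry the percentage of replicates containing the split
(support) and the mean branch length over those replicates.

The per-replicate tree engine is deliberately pluggable
(``rrhs_consensus(tree_builder=...)``): the consensus logic is independent
of how each replicate tree is inferred.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix


@dataclass
class HaplotypeMatrix:
    """Sites x isolates haploid alleles: 0=ref, 1=alt, -1=missing."""

    sites: pd.DataFrame
    isolates: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.sites), len(self.isolates)):
            raise ValueError("allele matrix shape mismatch")


def _isolate_stream(seed: int, rep: int, name: str) -> np.random.Generator:
    # keyed by isolate name so resolution (hence consensus support) is
    # invariant to isolate input order
    h = int.from_bytes(hashlib.blake2s(name.encode(), digest_size=4).digest(), "big")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, rep, h]))


def sample_haplotype(gm: GenotypeMatrix, seed: int, rep: int = 0) -> HaplotypeMatrix:
    """One pseudo-haploid resolution: hom sites copied, het sites drawn 50/50."""
    out = np.empty(gm.dosages.shape, dtype=np.int8)
    for j, name in enumerate(gm.isolates):
        col = gm.dosages[:, j]
        rng = _isolate_stream(seed, rep, name)
        draws = (rng.random(gm.n_sites) < 0.5).astype(np.int8)
        hap = np.where(col == 2, 1, 0).astype(np.int8)
        hap[col == 1] = draws[col == 1]
        hap[col == MISSING] = MISSING
        out[:, j] = hap
    return HaplotypeMatrix(sites=gm.sites, isolates=gm.isolates, alleles=out)


def pairwise_distance(hm: HaplotypeMatrix) -> np.ndarray:
    """p-distance matrix: mismatches / pairwise non-missing sites."""
    if len(hm.isolates) < 2:
        raise ValueError("need at least 2 isolates")
    H = hm.alleles
    valid = (H != MISSING).astype(np.float32)
    alt = ((H == 1) & (H != MISSING)).astype(np.float32)
    ref = ((H == 0)).astype(np.float32)
    shared = valid.T @ valid
    mismatch = alt.T @ ref + ref.T @ alt
    zero = shared == 0
    if zero.any():
        i, j = np.argwhere(zero)[0]
        raise ValueError(
            f"isolates {hm.isolates[i]!r} and {hm.isolates[j]!r} share no genotyped sites"
        )
    d = mismatch / shared
    np.fill_diagonal(d, 0.0)
    return ((d + d.T) / 2.0).astype(float)


# ---------------------------------------------------------------------------
# trees


class Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children: list | None = None):
        self.label = label
        self.children = children or []  # list of (Node, branch_length)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    root: Node
    leaves: list[str]

    def newick(self, support: dict | None = None) -> str:
        """Newick string; optional split->support labels on internal nodes."""

        def fmt(node: Node) -> str:
            if node.is_leaf():
                return node.label
            parts = ",".join(f"{fmt(ch)}:{bl:.10g}" for ch, bl in node.children)
            label = node.label or ""
            return f"({parts}){label}"

        return fmt(self.root) + ";"

    def splits(self) -> tuple[dict[frozenset, float], dict[str, float]]:
        """(internal splits -> branch length, leaf -> terminal branch length).

        Internal splits are canonicalised to the side *not* containing the
        lexicographically smallest leaf, making them invariant to input order.
        """
        all_leaves = frozenset(self.leaves)
        ref = min(self.leaves)
        internal: dict[frozenset, float] = {}
        terminal: dict[str, float] = {}

        def below(node: Node) -> frozenset:
            if node.is_leaf():
                return frozenset([node.label])
            members = frozenset()
            for ch, bl in node.children:
                b = below(ch)
                if len(b) == 1:
                    terminal[next(iter(b))] = bl
                elif len(b) <= len(all_leaves) - 2:
                    key = b if ref not in b else all_leaves - b
                    internal[key] = bl
                members |= b
            return members

        below(self.root)
        return internal, terminal


def build_tree(d: np.ndarray, labels: list[str]) -> Tree:
    """Neighbor joining with negative branch lengths clamped to zero and the
    deficit shifted to the adjacent branch (path lengths preserved)."""
    d = np.asarray(d, dtype=float)
    n_total = len(labels)
    if d.shape != (n_total, n_total):
        raise ValueError("distance matrix / label mismatch")
    if n_total == 1:
        return Tree(root=Node(label=labels[0]), leaves=list(labels))

    nodes: list[Node] = [Node(label=lab) for lab in labels]
    D = d.copy()
    active = list(range(n_total))

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        m = len(active)
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * sub[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = sub[i, j] - li
        li, lj = clamp_pair(li, lj)
        u = Node(children=[(nodes[idx[i]], li), (nodes[idx[j]], lj)])
        du = 0.5 * (sub[i, :] + sub[j, :] - sub[i, j])
        du = np.maximum(du, 0.0)
        # reuse slot idx[i] for the new node
        D[idx[i], idx] = du
        D[idx, idx[i]] = du
        D[idx[i], idx[i]] = 0.0
        nodes[idx[i]] = u
        active.remove(int(idx[j]))

    if len(active) == 3:
        a, b, c = active
        va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
        vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        va, vb, vc = (max(v, 0.0) for v in (va, vb, vc))
        root = Node(children=[(nodes[a], va), (nodes[b], vb), (nodes[c], vc)])
    else:  # two taxa
        a, b = active
        half = max(D[a, b] / 2.0, 0.0)
        root = Node(children=[(nodes[a], half), (nodes[b], half)])
    return Tree(root=root, leaves=list(labels))


# ---------------------------------------------------------------------------
# consensus


@dataclass
class ConsensusTree:
    """Majority-rule consensus: topology, mean branch lengths, replicate support."""

    newick: str
    leaves: list[str]
    splits: pd.DataFrame = field(repr=False)  # members, support, mean_length
    reps: int = 0

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick")

    def support_for(self, names) -> float:
        """Replicate support (%) for the split separating ``names`` from the rest.

        Returns 0 if the consensus contains no such split.
        """
        target = frozenset(names)
        comp = frozenset(self.leaves) - target
        for members, support in zip(self.splits["members"], self.splits["support"]):
            if members == target or members == comp:
                return float(support)
        return 0.0

    def rerooted_newick(self, outgroup) -> str:
        """Newick rerooted at the edge above ``outgroup`` (a leaf name or list)."""
        tree = self.to_dendropy()
        tree.is_rooted = True
        names = [outgroup] if isinstance(outgroup, str) else list(outgroup)
        taxa = [t for t in tree.taxon_namespace if t.label in names]
        if not taxa:
            raise ValueError(f"outgroup {outgroup!r} not in tree")
        mrca = tree.mrca(taxa=taxa)
        tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
        return tree.as_string(schema="newick", suppress_rooting=True).strip()


def _consensus_from_splits(
    leaves: list[str],
    split_support: dict[frozenset, float],
    split_length: dict[frozenset, float],
    terminal_length: dict[str, float],
) -> Tree:
    """Assemble the (compatible, laminar) majority splits into a tree."""
    ref = min(leaves)
    order = sorted(split_support, key=len)  # ascending size
    node_of: dict[frozenset, Node] = {s: Node() for s in order}
    root = Node()
    for pos, s in enumerate(order):
        parent = None
        for t in order[pos + 1 :]:
            if s < t:
                parent = t
                break
        node = node_of[s]
        node.label = f"{split_support[s]:.0f}"
        target = node_of[parent] if parent is not None else root
        target.children.append((node, split_length[s]))
    for leaf in leaves:
        if leaf == ref:
            root.children.append((Node(label=leaf), terminal_length[leaf]))
            continue
        parent = None
        for t in order:
            if leaf in t:
                parent = t
                break
        target = node_of[parent] if parent is not None else root
        target.children.append((Node(label=leaf), terminal_length[leaf]))
    # stable child order: leaves first alphabetically, then internals by size
    def sort_key(item):
        node, _ = item
        return (0, node.label) if node.is_leaf() else (1, len(node.children))

    for node in [root] + list(node_of.values()):
        node.children.sort(key=sort_key)
    return Tree(root=root, leaves=list(leaves))


def rrhs_consensus(
    gm: GenotypeMatrix,
    reps: int = 100,
    seed: int = 0,
    tree_builder=None,
    return_replicates: bool = False,
):
    """RRHS pipeline: sample haplotypes, build a tree per replicate, summarise.

    Splits occurring in more than 50% of replicates are retained; their
    support is the occurrence percentage and their branch length the mean
    over the replicates containing them.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    builder = tree_builder or build_tree
    count: dict[frozenset, int] = {}
    length_sum: dict[frozenset, float] = {}
    term_sum: dict[str, float] = {leaf: 0.0 for leaf in gm.isolates}
    replicate_trees: list[Tree] = []
    for r in range(reps):
        hm = sample_haplotype(gm, seed, rep=r)
        d = pairwise_distance(hm)
        tree = builder(d, gm.isolates)
        internal, terminal = tree.splits()
        for s, bl in internal.items():
            count[s] = count.get(s, 0) + 1
            length_sum[s] = length_sum.get(s, 0.0) + bl
        for leaf, bl in terminal.items():
            term_sum[leaf] += bl
        if return_replicates:
            replicate_trees.append(tree)
    majority = {s: c for s, c in count.items() if c > reps / 2}
    support = {s: 100.0 * c / reps for s, c in majority.items()}
    mean_len = {s: length_sum[s] / majority[s] for s in majority}
    term_mean = {leaf: v / reps for leaf, v in term_sum.items()}
    tree = _consensus_from_splits(gm.isolates, support, mean_len, term_mean)
    table = pd.DataFrame(
        {
            "members": list(majority.keys()),
            "support": [support[s] for s in majority],
            "mean_length": [mean_len[s] for s in majority],
        }
    ).sort_values("support", ascending=False, ignore_index=True)
    ct = ConsensusTree(newick=tree.newick(), leaves=list(gm.isolates), splits=table, reps=reps)
    if return_replicates:
        return ct, replicate_trees
    return ct
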