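"""Distance phylogenetics in the MEGA style: p-distance with pairwise
deletion, neighbor-joining, nonparametric bootstrap, and clade assignment.

The p-distance between two aligned protein sequences is the fraction of
mismatching residues among *comparable* sites — positions where neither
sequence carries a gap (pairwise deletion, as opposed to dropping any column
with a gap anywhere). Neighbor-joining then agglomerates taxa by the classic
Q-criterion; on additive inputs it recovers the generating tree, branch
lengths included. Internal-edge support is estimated by resampling alignment
columns with replacement and counting how often each bipartition of the
full-data tree reappears.

Amino-acid ambiguity codes (B, Z, X) are compared literally: they mismatch
every residue except an identical code. Negative NJ branch lengths are kept
internally and clamped to zero only when serializing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from ._util import rng_from

GAP = ord("-")


@dataclass
class ProteinAlignment:
    """Equal-length aligned protein sequences (gap character ``-``)."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows must have equal length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise ValueError(f"rows must share one length (got {sorted(lens)})")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), dtype=np.uint8).reshape(
            self.n_taxa, self.length
        )


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray
    comparable_sites: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


class TreeNode:
    __slots__ = ("name", "children", "length", "support")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.children: list["TreeNode"] = []
        self.length = length  # branch to parent; meaningless at the root
        self.support: Optional[float] = None

    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.walk() if n.is_leaf())


@dataclass
class PhyloTree:
    """Unrooted tree stored rooted at an internal (trifurcating) node."""

    root: TreeNode
    taxa: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.taxa = sorted(self.root.leaf_names())

    # -- structure -------------------------------------------------------
    def n_edges(self) -> int:
        return sum(1 for n in self.root.walk() if n is not self.root)

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial splits, each as a frozenset of its two leaf sides."""
        all_taxa = frozenset(self.taxa)
        out = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf():
                continue
            side = node.leaf_names()
            other = all_taxa - side
            if len(side) >= 2 and len(other) >= 2:
                out.add(frozenset((side, other)))
        return out

    def internal_nodes(self) -> list[TreeNode]:
        return [
            n
            for n in self.root.walk()
            if n is not self.root and not n.is_leaf()
        ]

    # -- distances -------------------------------------------------------
    def patristic_distances(self) -> tuple[list[str], np.ndarray]:
        """All-pairs leaf-to-leaf path lengths (raw branch lengths, no clamp)."""
        adj: dict[int, list[tuple[int, float]]] = {}
        leaves: dict[str, int] = {}
        ids: dict[int, TreeNode] = {}

        def build(node: TreeNode) -> None:
            ids[id(node)] = node
            if node.is_leaf():
                leaves[node.name] = id(node)
            for c in node.children:
                adj.setdefault(id(node), []).append((id(c), c.length))
                adj.setdefault(id(c), []).append((id(node), c.length))
                build(c)

        build(self.root)
        taxa = sorted(leaves)
        n = len(taxa)
        dm = np.zeros((n, n))
        for i, t in enumerate(taxa):
            # single-source traversal over the (acyclic) adjacency
            dist = {leaves[t]: 0.0}
            stack = [leaves[t]]
            while stack:
                u = stack.pop()
                for v, w in adj.get(u, []):
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, s in enumerate(taxa):
                dm[i, j] = dist[leaves[s]]
        np.fill_diagonal(dm, 0.0)
        return taxa, dm

    # -- serialization ---------------------------------------------------
    def newick(self, support_min: Optional[float] = None) -> str:
        """Newick with branch lengths (negatives clamped to 0) and integer
        support labels on internal nodes; ``support_min`` hides weaker ones."""

        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.name}:{max(node.length, 0.0):.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if node.support is not None and (
                support_min is None or node.support >= support_min
            ):
                label = str(int(round(node.support)))
            if node is self.root:
                return f"({inner}){label}"
            return f"({inner}){label}:{max(node.length, 0.0):.10g}"

        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# p-distance


def p_distance_matrix(aln: ProteinAlignment) -> DistanceMatrix:
    """Pairwise-deletion p-distances: mismatches / sites gap-free in both rows.

    Raises ``ValueError`` naming the offending pair if two sequences share no
    comparable site.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least two sequences")
    arr = aln.to_array()
    ok = arr != GAP
    n = aln.n_taxa
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            c = int(both.sum())
            if c == 0:
                raise ValueError(
                    f"no comparable sites between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
                )
            mm = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = mm / c
            comp[i, j] = comp[j, i] = c
    return DistanceMatrix(list(aln.taxa), d, comp)


# ---------------------------------------------------------------------------
# neighbor-joining


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classic NJ (Saitou-Nei with the standard Q-criterion).

    Ties in Q are broken by the lowest (row, column) index pair so the result
    is reproducible; additive inputs are recovered exactly, including branch
    lengths (possibly negative; clamped only on output).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    nodes = [TreeNode(t) for t in dm.taxa]
    d = dm.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin scans row-major, so equal minima resolve to the lowest (i, j)
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.children = [nodes[i], nodes[j]]

        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    # terminal star: three branches solved by the three-point equations
    root = TreeNode()
    (a, b, c) = nodes
    a.length = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    b.length = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    c.length = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root.children = [a, b, c]
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    aln: ProteinAlignment, n_reps: int = 1000, seed: int = 0
) -> PhyloTree:
    """Column-resampling bootstrap supports on the full-data NJ tree.

    Each replicate resamples alignment columns with replacement, rebuilds a
    p-distance NJ tree, and the support of each internal edge of the
    full-data tree is the percentage of replicates whose tree contains the
    same bipartition. Replicates in which some pair has no comparable site
    are dropped; more than 10% drops aborts the analysis.
    """
    if aln.n_taxa < 4:
        raise ValueError("supports are only informative for >= 4 taxa")
    full = neighbor_joining(p_distance_matrix(aln))
    target = {bp: 0 for bp in full.bipartitions()}

    rng = rng_from(seed)
    arr = aln.to_array()
    dropped = 0
    used = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        sub = arr[:, cols]
        rows = ["".join(map(chr, row)) for row in sub]
        try:
            dm = p_distance_matrix(ProteinAlignment(list(aln.taxa), rows))
        except ValueError:
            dropped += 1
            continue
        used += 1
        for bp in neighbor_joining(dm).bipartitions():
            if bp in target:
                target[bp] += 1
    if dropped >= 0.1 * n_reps:
        raise ValueError(
            f"{dropped}/{n_reps} bootstrap replicates had incomparable pairs"
        )
    if used == 0:
        raise ValueError("no usable bootstrap replicates")

    all_taxa = frozenset(full.taxa)
    for node in full.internal_nodes():
        side = node.leaf_names()
        bp = frozenset((side, all_taxa - side))
        if bp in target:
            node.support = 100.0 * target[bp] / used
    return full


# ---------------------------------------------------------------------------
# clade assignment


def assign_clade(
    query_taxa: Sequence[str],
    tree: PhyloTree,
    reference_clades: dict[str, str],
    rel_tol: float = 1e-12,
) -> dict[str, Optional[str]]:
    """Assign each query leaf the clade of its nearest labeled reference leaf
    by patristic distance; exact ties between clades yield ``None``."""
    taxa, dm = tree.patristic_distances()
    pos = {t: k for k, t in enumerate(taxa)}
    for q in query_taxa:
        if q not in pos:
            raise ValueError(f"query {q!r} is not a leaf of the tree")
    refs = [t for t in taxa if t in reference_clades]
    if not refs:
        raise ValueError("no reference leaf carries a clade label")
    out: dict[str, Optional[str]] = {}
    for q in query_taxa:
        dists = [(dm[pos[q], pos[t]], t) for t in refs]
        best = min(d for d, _ in dists)
        clades = {
            reference_clades[t]
            for d, t in dists
            if d <= best + rel_tol * max(best, 1.0)
        }
        out[q] = clades.pop() if len(clades) == 1 else None
    return out
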