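"""p-distance, neighbor-joining, bootstrap, and clade assignment."""

import numpy as np
import pytest

import dgekit as dk
from dgekit.phylogeny import (
    DistanceMatrix,
    PhyloTree,
    ProteinAlignment,
    TreeNode,
    assign_clade,
    bootstrap_support,
    neighbor_joining,
    p_distance_matrix,
)


def random_additive(rng, n_taxa):
    """Random unrooted binary tree with known path-length matrix."""
    nodes = [TreeNode(f"t{i}") for i in range(n_taxa)]
    pool = list(nodes)
    while len(pool) > 3:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        a, b = pool[j], pool[i]
        parent = TreeNode()
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        parent.children = [b, a]
        pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [parent]
    root = TreeNode()
    for p in pool:
        p.length = float(rng.uniform(0.05, 1.0))
    root.children = pool
    tree = PhyloTree(root)
    taxa, d = tree.patristic_distances()
    return tree, DistanceMatrix(taxa, d)


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = ProteinAlignment(["a", "b"], ["ACDEF", "ACDEF"])
        assert np.allclose(p_distance_matrix(aln).d, 0)

    def test_hand_enumerated_pair(self):
        aln = ProteinAlignment(["a", "b"], ["ACG-TT", "ACGAAT"])
        dm = p_distance_matrix(aln)
        assert dm.comparable_sites[0, 1] == 5
        assert dm.d[0, 1] == pytest.approx(0.2)

    def test_permutation_equivariant(self, rng):
        aln = dk.generate_alignment(6, length=80, mutation_rate=0.2, gap_rate=0.1, seed=8)
        dm = p_distance_matrix(aln)
        perm = rng.permutation(6)
        aln2 = ProteinAlignment([aln.taxa[i] for i in perm], [aln.rows[i] for i in perm])
        dm2 = p_distance_matrix(aln2)
        assert np.allclose(dm2.d, dm.d[np.ix_(perm, perm)])

    def test_shared_gap_columns_ignored(self):
        base = dk.generate_alignment(4, length=60, mutation_rate=0.2, seed=9)
        padded = ProteinAlignment(base.taxa, [r + "----" for r in base.rows])
        assert np.allclose(p_distance_matrix(base).d, p_distance_matrix(padded).d)

    def test_bounded(self):
        aln = dk.generate_alignment(5, length=100, mutation_rate=0.9, seed=10)
        d = p_distance_matrix(aln).d
        assert np.all(d >= 0) and np.all(d <= 1)

    def test_incomparable_pair_identified(self):
        aln = ProteinAlignment(["a", "b", "c"], ["AC--", "--DE", "ACDE"])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            p_distance_matrix(aln)


class TestNeighborJoining:
    def test_worked_four_taxon_example(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], d))
        assert tree.bipartitions() == {
            frozenset((frozenset({"A", "B"}), frozenset({"C", "D"})))
        }
        lengths = {}
        for node in tree.root.walk():
            if node.is_leaf():
                lengths[node.name] = node.length
            elif node is not tree.root:
                lengths["internal"] = node.length
        assert lengths == pytest.approx(
            {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "internal": 1.0}
        )

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        got = {n.name: n.length for n in tree.root.children}
        assert got == pytest.approx({"a": 0.0, "b": 2.0, "c": 3.0})

    def test_recovers_random_additive_matrices(self, rng):
        """Path-length oracle: NJ must reproduce the generating topology and
        its patristic matrix exactly on additive inputs."""
        for _ in range(30):
            n = int(rng.integers(5, 13))
            true_tree, dm = random_additive(rng, n)
            est = neighbor_joining(dm)
            assert est.bipartitions() == true_tree.bipartitions()
            taxa, d_est = est.patristic_distances()
            assert taxa == dm.taxa
            assert np.allclose(d_est, dm.d, atol=1e-9)

    def test_agrees_with_skbio_on_noisy_matrix(self):
        """Independent implementation check on a non-additive matrix."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj

        rng = np.random.default_rng(3)
        _, dm = random_additive(rng, 8)
        noisy = dm.d + rng.uniform(0, 0.05, dm.d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        ours = neighbor_joining(DistanceMatrix(dm.taxa, noisy))
        theirs = nj(SkDM(noisy, ids=dm.taxa))
        their_bps = set()
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            other = frozenset(dm.taxa) - side
            if len(side) >= 2 and len(other) >= 2:
                their_bps.add(frozenset((side, other)))
        assert ours.bipartitions() == their_bps

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], d)

    def test_edge_count(self, rng):
        _, dm = random_additive(rng, 9)
        assert neighbor_joining(dm).n_edges() == 2 * 9 - 3


def homoplasy_free_alignment(n_cols=50):
    """4 taxa where every variable column supports AB|CD."""
    a = "A" * n_cols
    c = "C" * n_cols
    return ProteinAlignment(["A", "B", "C", "D"], [a, a, c, c])


class TestBootstrap:
    def test_homoplasy_free_full_support(self):
        tree = bootstrap_support(homoplasy_free_alignment(), n_reps=1000, seed=11)
        (node,) = tree.internal_nodes()
        assert node.support == pytest.approx(100.0)

    def test_single_replicate_support_binary(self):
        aln = dk.generate_alignment(5, length=60, mutation_rate=0.3, seed=12)
        tree = bootstrap_support(aln, n_reps=1, seed=13)
        for node in tree.internal_nodes():
            assert node.support in (0.0, 100.0)

    def test_bit_reproducible(self):
        aln = dk.generate_alignment(6, length=80, mutation_rate=0.3, seed=14)
        a = bootstrap_support(aln, n_reps=50, seed=15).newick()
        b = bootstrap_support(aln, n_reps=50, seed=15).newick()
        assert a == b

    def test_seed_stability_of_supports(self):
        """Supports estimated from two independent streams agree closely at
        1000 replicates (column resampling is exchangeable)."""
        aln = dk.generate_alignment(6, length=120, mutation_rate=0.25, seed=16)
        t1 = bootstrap_support(aln, n_reps=1000, seed=17)
        t2 = bootstrap_support(aln, n_reps=1000, seed=18)
        s1 = sorted(n.support for n in t1.internal_nodes())
        s2 = sorted(n.support for n in t2.internal_nodes())
        assert all(abs(a - b) <= 5.0 for a, b in zip(s1, s2))

    def test_gappy_alignment_rejected(self):
        # one pair comparable only at a single column: most replicates drop
        rows = ["AA" + "-" * 40, "-A" + "C" * 40, "CA" + "C" * 40, "GA" + "G" * 40]
        aln = ProteinAlignment(["a", "b", "c", "d"], rows)
        with pytest.raises(ValueError, match="replicates"):
            bootstrap_support(aln, n_reps=100, seed=19)

    def test_newick_support_filter(self):
        tree = bootstrap_support(homoplasy_free_alignment(), n_reps=10, seed=20)
        assert ")100:" in tree.newick(support_min=70)
        hidden = bootstrap_support(
            dk.generate_alignment(5, 40, mutation_rate=0.4, seed=21), n_reps=10, seed=22
        )
        # labels below the threshold are omitted
        nwk = hidden.newick(support_min=101)
        assert not any(ch.isdigit() and nwk[i - 1] == ")" for i, ch in enumerate(nwk))


class TestAssignClade:
    def make_tree(self):
        d = np.array(
            [[0, 0.2, 0.8, 0.9], [0.2, 0, 0.8, 0.9], [0.8, 0.8, 0, 0.3], [0.9, 0.9, 0.3, 0]]
        )
        return neighbor_joining(DistanceMatrix(["q", "refB", "refF", "refG"], d))

    def test_nearest_reference(self):
        tree = self.make_tree()
        out = assign_clade(["q"], tree, {"refB": "B", "refF": "F", "refG": "G"})
        assert out == {"q": "B"}

    def test_exact_tie_unassigned(self):
        d = np.array([[0, 0.4, 0.4], [0.4, 0, 0.2], [0.4, 0.2, 0]])
        tree = neighbor_joining(DistanceMatrix(["q", "f", "g"], d))
        out = assign_clade(["q"], tree, {"f": "F", "g": "G"})
        assert out == {"q": None}

    def test_missing_query_rejected(self):
        with pytest.raises(ValueError):
            assign_clade(["nope"], self.make_tree(), {"refB": "B"})

    def test_simulated_clades_recovered(self):
        """Clade-structured generation: queries join their own clade's
        references almost always at low mutation rates."""
        rng = np.random.default_rng(23)
        # two clades hanging off a long central branch
        root = TreeNode()
        clades = {}
        for cname, blen in (("X", 0.1), ("Y", 0.1)):
            anc = TreeNode(length=2.0)
            for k in range(4):
                leaf = TreeNode(f"{cname}{k}", length=blen)
                anc.children.append(leaf)
                clades[f"{cname}{k}"] = cname
            root.children.append(anc)
        root.children.append(TreeNode("out", 3.0))
        guide = PhyloTree(root)
        aln = dk.generate_alignment(9, length=400, mutation_rate=0.5, guide_tree=guide, seed=24)
        tree = neighbor_joining(p_distance_matrix(aln))
        refs = {t: clades[t] for t in clades if t.endswith(("0", "1"))}
        queries = [t for t in clades if t not in refs]
        out = assign_clade(queries, tree, refs)
        correct = sum(out[q] == clades[q] for q in queries)
        assert correct >= int(0.95 * len(queries))
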