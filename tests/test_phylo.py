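import numpy as np
import pytest

from agpepscan import synthdata
from agpepscan.phylo import (
    Alignment,
    DistanceMatrix,
    TreeNode,
    as_alignment,
    bipartitions,
    bootstrap_support,
    cut_groups,
    neighbor_joining,
    p_distance,
)
from agpepscan.seqio import ProteinRecord


def tree_path_lengths(tree):
    """Leaf-to-leaf path lengths of a TreeNode, as a dict of label pairs."""
    adj = {}

    def walk(node):
        for c, bl in node.children:
            adj.setdefault(id(node), []).append((id(c), bl))
            adj.setdefault(id(c), []).append((id(node), bl))
            walk(c)

    walk(tree)
    leaves = {id(l): l.label for l in tree.leaves()}
    out = {}
    for lid, lab in leaves.items():
        d = {lid: 0.0}
        stack = [lid]
        while stack:
            u = stack.pop()
            for v, bl in adj[u]:
                if v not in d:
                    d[v] = d[u] + bl
                    stack.append(v)
        for l2, lab2 in leaves.items():
            out[(lab, lab2)] = d[l2]
    return out


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(["a", "b"], ["ACDE", "ACDE"])
        assert p_distance(aln).values[0, 1] == 0

    def test_one_mismatch_in_four(self):
        aln = Alignment(["a", "b"], ["AAAA", "AAAT"])
        assert p_distance(aln).values[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_excludes_gapped_columns(self):
        aln = Alignment(["a", "b"], ["A-CD", "AB-D"])
        # comparable columns: 1 and 4, both matching
        assert p_distance(aln).values[0, 1] == 0.0

    def test_no_comparable_sites_errors(self):
        aln = Alignment(["a", "b"], ["A-", "-A"])
        with pytest.raises(ValueError, match="comparable"):
            p_distance(aln)

    def test_poisson_correction(self):
        aln = Alignment(["a", "b"], ["AAAA", "AAAT"])
        d = p_distance(aln, model="poisson").values[0, 1]
        assert d == pytest.approx(-np.log(0.75))

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            Alignment(["a", "b"], ["AA", "AAA"])

    def test_as_alignment_requires_equal_lengths(self):
        with pytest.raises(ValueError, match="aligner"):
            as_alignment([ProteinRecord("a", "AA"), ProteinRecord("b", "AAA")])


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(["A", "B", "C"], np.array(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = neighbor_joining(D)
        lengths = {c.label: bl for c, bl in tree.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> additive distances
        D = DistanceMatrix(
            list("ABCD"),
            np.array(
                [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
            ),
        )
        tree = neighbor_joining(D)
        assert bipartitions(tree) == {
            frozenset([frozenset("AB"), frozenset("CD")])
        }
        paths = tree_path_lengths(tree)
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                assert paths[(a, b)] == pytest.approx(D.values[i, j], abs=1e-12)

    def test_equidistant_taxa_zero_internal_branch(self):
        D = DistanceMatrix(list("ABCD"), 2.0 * (1 - np.eye(4)))
        tree = neighbor_joining(D)
        paths = tree_path_lengths(tree)
        assert paths[("A", "B")] == pytest.approx(2.0)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))

    @pytest.mark.parametrize("seed", range(25))
    def test_consistency_on_random_additive_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        ids, D, true_bps = synthdata.gen_additive_tree(n, seed=seed)
        tree = neighbor_joining(DistanceMatrix(ids, D))
        assert bipartitions(tree) == true_bps
        paths = tree_path_lengths(tree)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                assert abs(paths[(a, b)] - D[i, j]) < 1e-9

    def test_leaf_permutation_gives_isomorphic_tree(self):
        ids, D, _ = synthdata.gen_additive_tree(7, seed=3)
        tree1 = neighbor_joining(DistanceMatrix(ids, D))
        perm = np.random.default_rng(0).permutation(len(ids))
        ids2 = [ids[i] for i in perm]
        tree2 = neighbor_joining(DistanceMatrix(ids2, D[np.ix_(perm, perm)]))
        assert bipartitions(tree1) == bipartitions(tree2)
        p1, p2 = tree_path_lengths(tree1), tree_path_lengths(tree2)
        for key in p1:
            assert p1[key] == pytest.approx(p2[key], abs=1e-9)

    def test_agrees_with_skbio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj

        ids, D, _ = synthdata.gen_additive_tree(7, seed=9)
        sk = nj(skbio.DistanceMatrix(D, ids))
        allset = frozenset(ids)
        sk_bps = set()
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(ids) - 1:
                sk_bps.add(frozenset([side, allset - side]))
        ours = bipartitions(neighbor_joining(DistanceMatrix(ids, D)))
        assert ours == sk_bps


class TestBootstrap:
    aln = Alignment(
        ["a", "b", "c", "d", "e"],
        ["AAAAAAAAAA", "AAAAAAAAAA", "CCCCCCCCCC", "GGGGGGGGGG", "GGGGGTTTTT"],
    )

    def test_identical_pair_supported_at_100(self):
        tree = bootstrap_support(self.aln, replicates=50, seed=1)
        pair_nodes = [
            n for n in _internal(tree) if sorted(n.leaf_labels()) == ["a", "b"]
        ]
        assert pair_nodes and pair_nodes[0].support == 100.0

    def test_zero_replicates_gives_plain_tree(self):
        tree = bootstrap_support(self.aln, replicates=0, seed=1)
        assert all(n.support is None for n in _internal(tree))

    def test_fixed_seed_is_bit_identical(self):
        t1 = bootstrap_support(self.aln, replicates=40, seed=7)
        t2 = bootstrap_support(self.aln, replicates=40, seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_too_few_sequences_rejected(self):
        aln = Alignment(["a", "b", "c"], ["AA", "AC", "CC"])
        with pytest.raises(ValueError, match="at least 4"):
            bootstrap_support(aln, replicates=10, seed=0)


def _internal(tree):
    out = []

    def walk(node):
        if not node.is_leaf:
            out.append(node)
            for c, _ in node.children:
                walk(c)

    walk(tree)
    return out


class TestCutGroups:
    def test_k1_single_group(self):
        ids, D, _ = synthdata.gen_additive_tree(6, seed=2)
        tree = neighbor_joining(DistanceMatrix(ids, D))
        assert set(cut_groups(tree, 1).values()) == {1}

    def test_long_edge_splits_caterpillar(self):
        # two tight cherries joined by one long internal edge
        D = np.array(
            [
                [0, 0.2, 10, 10.2],
                [0.2, 0, 10.2, 10.4],
                [10, 10.2, 0, 0.2],
                [10.2, 10.4, 0.2, 0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), D))
        groups = cut_groups(tree, 2)
        assert groups["A"] == groups["B"] != groups["C"] == groups["D"]

    def test_three_planted_clades_recovered(self):
        rng = np.random.default_rng(4)
        sizes = (5, 4, 3)
        # block-structured distances: tiny within clades, large between
        n = sum(sizes)
        labels = np.repeat(np.arange(3), sizes)
        D = np.where(labels[:, None] == labels[None, :], 0.1, 8.0)
        D += rng.uniform(0, 0.01, (n, n))
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0)
        ids = [f"s{i}" for i in range(n)]
        tree = neighbor_joining(DistanceMatrix(ids, D))
        groups = cut_groups(tree, 3)
        recovered = {}
        for i, leaf in enumerate(ids):
            recovered.setdefault(groups[leaf], set()).add(int(labels[i]))
        assert all(len(v) == 1 for v in recovered.values())
        assert len(recovered) == 3


class TestNewick:
    def test_roundtrippable_by_skbio(self):
        skbio = pytest.importorskip("skbio")
        ids, D, _ = synthdata.gen_additive_tree(6, seed=8)
        tree = neighbor_joining(DistanceMatrix(ids, D))
        parsed = skbio.TreeNode.read([tree.to_newick()])
        assert sorted(t.name for t in parsed.tips()) == sorted(ids)
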