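import numpy as np
import pytest

from lstscreen.phylo import (
    AlignmentError,
    DistanceMatrix,
    ProteinAlignment,
    SupportTree,
    TreeNode,
    bootstrap_support,
    congruence_test,
    neighbor_joining,
    p_distance,
)
from lstscreen.simulate import random_tree, simulate_alignment


def aln(*pairs):
    return ProteinAlignment([p[0] for p in pairs], [p[1] for p in pairs])


class TestAlignment:
    def test_rejects_fewer_than_three(self):
        with pytest.raises(AlignmentError):
            aln(("a", "AAA"), ("b", "AAA"))

    def test_rejects_ragged_rows(self):
        with pytest.raises(AlignmentError):
            aln(("a", "AAA"), ("b", "AA"), ("c", "AAA"))

    def test_fasta_round_trip(self, tmp_path):
        alignment = aln(("a", "ACD-"), ("b", "ACDE"), ("c", "AC-E"))
        alignment.to_fasta(tmp_path / "aln.fasta")
        back = ProteinAlignment.from_fasta(tmp_path / "aln.fasta")
        assert back.ids == alignment.ids
        assert np.array_equal(back.matrix, alignment.matrix)


class TestPDistance:
    def test_identical_sequences(self):
        d = p_distance(aln(("a", "AAAA"), ("b", "AAAA"), ("c", "AAAA")))
        assert d["a", "b"] == 0.0

    def test_half_mismatch(self):
        d = p_distance(aln(("a", "AAAA"), ("b", "AATT"), ("c", "AAAA")))
        assert d["a", "b"] == 0.5

    def test_pairwise_gap_deletion(self):
        # comparable columns between a and b: positions 3,4 -> one mismatch
        d = p_distance(aln(("a", "--AT"), ("b", "CCAA"), ("c", "CCAA")))
        assert d["a", "b"] == 0.5

    def test_no_comparable_columns_is_one(self, caplog):
        d = p_distance(aln(("a", "AA--"), ("b", "--CC"), ("c", "AACC")))
        assert d["a", "b"] == 1.0

    def test_matches_column_by_column_brute_force(self):
        rng = np.random.default_rng(5)
        letters = np.array(list("ACDEFG-"))
        rows = ["".join(rng.choice(letters, 60)) for _ in range(6)]
        alignment = aln(*[(f"s{i}", row) for i, row in enumerate(rows)])
        d = p_distance(alignment)
        for i in range(6):
            for j in range(6):
                mism = comp = 0
                for x, y in zip(rows[i], rows[j]):
                    if x == "-" or y == "-":
                        continue
                    comp += 1
                    mism += x != y
                expected = mism / comp if comp else 1.0
                assert d.matrix[i, j] == pytest.approx(expected)


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            DistanceMatrix(list("abc"), m)

    def test_nonzero_diagonal_rejected(self):
        m = np.array([[1.0, 1, 1], [1, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(list("abc"), m)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("abc"), m))
        lengths = {child.name: length for child, length in tree.root.children}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):3,C:4,D:5) -> pairwise path lengths
        m = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), m))
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert tree.path_distance(a, b) == pytest.approx(m[i, j])
        # the A|B vs C|D split, keyed by the side not containing leaf A
        assert frozenset({"C", "D"}) in tree.bipartitions()

    def test_eight_taxon_additive_path_lengths(self):
        rng = np.random.default_rng(2)
        leaves = [f"L{i}" for i in range(8)]
        source = random_tree(leaves, rng)
        m = np.zeros((8, 8))
        for i in range(8):
            for j in range(i + 1, 8):
                m[i, j] = m[j, i] = source.path_distance(leaves[i], leaves[j])
        recovered = neighbor_joining(DistanceMatrix(leaves, m))
        for i in range(8):
            for j in range(i + 1, 8):
                assert abs(recovered.path_distance(leaves[i], leaves[j]) - m[i, j]) < 1e-9

    def test_topology_recovery_on_random_additive_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(4, 11))
            leaves = [f"t{i}" for i in range(n)]
            source = random_tree(leaves, rng)
            m = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    m[i, j] = m[j, i] = source.path_distance(leaves[i], leaves[j])
            recovered = neighbor_joining(DistanceMatrix(leaves, m))
            assert set(recovered.bipartitions()) == set(source.bipartitions())

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_negative_branch_clamped_to_zero(self):
        # near-degenerate matrix known to produce a negative NJ branch
        m = np.array(
            [[0, 0.1, 0.4, 0.5], [0.1, 0, 0.45, 0.55], [0.4, 0.45, 0, 0.1], [0.5, 0.55, 0.1, 0]]
        )
        tree = neighbor_joining(DistanceMatrix(list("abcd"), m))

        def all_lengths(node):
            for child, length in node.children:
                yield length
                yield from all_lengths(child)

        assert all(length >= 0 for length in all_lengths(tree.root))


@pytest.fixture(scope="module")
def two_clade_alignment():
    # 20 invariant diagnostic columns separating the clades, plus noise
    rng = np.random.default_rng(0)
    noise = rng.choice(list("ACDEFGHIKL"), size=(6, 80))
    rows = ["".join(row) for row in noise]
    clade_a = ["A" * 20 + rows[i] for i in range(3)]
    clade_b = ["W" * 20 + rows[i] for i in range(3, 6)]
    return ProteinAlignment(["a1", "a2", "a3", "b1", "b2", "b3"], clade_a + clade_b)


class TestBootstrap:
    def test_separating_edge_strongly_supported(self, two_clade_alignment):
        tree = bootstrap_support(two_clade_alignment, n_reps=100, seed=1)
        bips = tree.bipartitions()
        separating = frozenset({"b1", "b2", "b3"})
        assert separating in bips
        assert bips[separating].support >= 95

    def test_single_replicate_supports_binary(self, two_clade_alignment):
        tree = bootstrap_support(two_clade_alignment, n_reps=1, seed=5)
        supports = {node.support for node in tree.bipartitions().values()}
        assert supports <= {0.0, 100.0}

    def test_same_seed_identical(self, two_clade_alignment):
        t1 = bootstrap_support(two_clade_alignment, n_reps=50, seed=9)
        t2 = bootstrap_support(two_clade_alignment, n_reps=50, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_leaf_order_permutation_invariant(self, two_clade_alignment):
        rng = np.random.default_rng(4)
        order = list(rng.permutation(two_clade_alignment.ids))
        permuted = two_clade_alignment.reorder(order)
        t1 = bootstrap_support(two_clade_alignment, n_reps=50, seed=3)
        t2 = bootstrap_support(permuted, n_reps=50, seed=3)
        s1 = {bip: node.support for bip, node in t1.bipartitions().items()}
        s2 = {bip: node.support for bip, node in t2.bipartitions().items()}
        assert s1 == s2

    def test_zero_reps_rejected(self, two_clade_alignment):
        with pytest.raises(ValueError):
            bootstrap_support(two_clade_alignment, n_reps=0)


def balanced_tree():
    """((q:.1,d1:.1):.4,(d2:.1,d3:.1):.4,(o1:.5,(o2:.2,o3:.2):.3):.1)"""
    def leaf(name):
        return TreeNode(name=name)

    root = TreeNode(
        children=[
            (TreeNode(children=[(leaf("q"), 0.1), (leaf("d1"), 0.1)]), 0.4),
            (TreeNode(children=[(leaf("d2"), 0.1), (leaf("d3"), 0.1)]), 0.4),
            (
                TreeNode(
                    children=[
                        (leaf("o1"), 0.5),
                        (TreeNode(children=[(leaf("o2"), 0.2), (leaf("o3"), 0.2)]), 0.3),
                    ]
                ),
                0.1,
            ),
        ]
    )
    return SupportTree(root)


class TestCongruence:
    def test_query_inside_donor_clade_supported(self):
        result = congruence_test(balanced_tree(), "q", {"d1", "d2", "d3"}, {"o1", "o2", "o3"})
        assert result.supported
        assert "d1" in result.sister_leaves

    def test_query_sister_to_outgroup_unsupported(self):
        result = congruence_test(balanced_tree(), "o1", {"d1"}, {"o2", "o3"})
        assert not result.supported

    def test_minimal_three_leaf_tree(self):
        root = TreeNode(
            children=[
                (TreeNode(name="q"), 0.1),
                (TreeNode(name="d"), 0.15),
                (TreeNode(name="o"), 0.9),
            ]
        )
        result = congruence_test(SupportTree(root), "q", {"d"}, {"o"})
        # midpoint rooting pushes the long o edge away: q groups with d
        assert result.supported

    def test_rerooting_invariance(self):
        import dendropy

        base = balanced_tree()
        expected = congruence_test(base, "q", {"d1", "d2", "d3"}, {"o1", "o2", "o3"})
        tree = dendropy.Tree.get(data=base.to_newick(), schema="newick")
        for leaf_label in ("o1", "d3"):
            rerooted = dendropy.Tree.get(data=base.to_newick(), schema="newick")
            node = [l for l in rerooted.leaf_node_iter() if l.taxon.label == leaf_label][0]
            rerooted.reroot_at_edge(node.edge, update_bipartitions=False)
            variant = SupportTree(_from_dendropy(rerooted.seed_node))
            got = congruence_test(variant, "q", {"d1", "d2", "d3"}, {"o1", "o2", "o3"})
            assert got.supported == expected.supported

    def test_unknown_leaf_raises(self):
        with pytest.raises(KeyError):
            congruence_test(balanced_tree(), "nope", {"d1"}, {"o1"})

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            congruence_test(balanced_tree(), "q", {"d1"}, {"d1"})


def _from_dendropy(node):
    if node.is_leaf():
        return TreeNode(name=node.taxon.label)
    out = TreeNode()
    for child in node.child_nodes():
        out.children.append((_from_dendropy(child), child.edge.length or 0.0))
    return out


class TestSimulatedAlignments:
    def test_vanishing_rate_gives_identical_sequences(self):
        alignment = simulate_alignment(
            "((d1:1,d2:1):2,(o1:1,o2:1):2);", None, 60, 1e-9, 3
        )
        assert len({alignment.sequence(i) for i in range(len(alignment.ids))}) == 1

    def test_query_in_donor_clade_recovered(self):
        hits = 0
        for seed in range(30):
            alignment = simulate_alignment(
                "((d1:1,d2:1):2,(o1:1,o2:1):2);", "d1", 200, 0.1, seed
            )
            tree = neighbor_joining(p_distance(alignment))
            result = congruence_test(tree, "query", {"d1", "d2"}, {"o1", "o2"})
            hits += result.supported
        assert hits >= 27  # >= 95% recovery at scale; slack for 30 replicates

    def test_longer_paths_give_larger_p_distance(self):
        newick = "(((a:0.5,b:0.5):0.5,c:1):0.5,d:3);"
        totals = {"ab": 0.0, "ac": 0.0, "ad": 0.0}
        for seed in range(50):
            alignment = simulate_alignment(newick, None, 150, 0.15, seed)
            d = p_distance(alignment)
            totals["ab"] += d["a", "b"]
            totals["ac"] += d["a", "c"]
            totals["ad"] += d["a", "d"]
        assert totals["ab"] < totals["ac"] < totals["ad"]

    def test_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            simulate_alignment("((a:1,b:1):1,c:1);", None, 60, 0.9, 1)
        with pytest.raises(ValueError):
            simulate_alignment("((a:1,b:1):1,c:1);", None, 10, 0.1, 1)
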