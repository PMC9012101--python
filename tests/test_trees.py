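"""NJ, Fitch parsimony, consensus, RF, rooting, pruning, newick IO."""

import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from funcphylo import synthetic
from funcphylo import trees as T
from funcphylo.profiles import BinaryMatrix, DistanceMatrix


def binary_matrix(rows, labels=None):
    values = np.asarray(rows, dtype=np.uint8)
    labels = labels or [f"L{i}" for i in range(values.shape[0])]
    cols = tuple(f"c{j:03d}" for j in range(values.shape[1]))
    return BinaryMatrix(tuple(labels), cols, values)


def brute_force_fitch(adj, values):
    """Minimum changes over all 0/1 assignments to internal nodes."""
    internals = sorted(k for k in adj if len(adj[k]) > 1)
    leaves = sorted(k for k in adj if len(adj[k]) == 1)
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    total = 0
    for col in range(values.shape[1]):
        best = None
        for assign in itertools.product((0, 1), repeat=len(internals)):
            st = dict(zip(internals, assign))
            st.update({l: values[l, col] for l in leaves})
            changes = sum(1 for u, v in edges if st[u] != st[v])
            best = changes if best is None or changes < best else best
        total += best
    return total


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        # distances {2,3,4} scaled into [0,1]; NJ is scale-equivariant
        dm = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]]) / 4.0,
        )
        tree = T.neighbor_joining(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx(
            {"A": 0.5 / 4, "B": 1.5 / 4, "C": 2.5 / 4}
        )

    def test_four_taxon_additive_recovery(self):
        gen = T.parse_newick("((A:1,B:2):1,(C:3,D:4):0);")
        dm, scale = T.path_distance_matrix(gen)
        tree = T.neighbor_joining(dm)
        assert T.rf_distance(tree, gen) == 0
        rec, scale2 = T.path_distance_matrix(tree)
        np.testing.assert_allclose(
            rec.values * scale2, dm.values, atol=1e-9
        )

    def test_consistency_on_random_additive_matrices(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 21))
            gen = synthetic.random_binary_tree(n, rng)
            dm, scale = T.path_distance_matrix(gen)
            tree = T.neighbor_joining(dm)
            assert T.rf_distance(tree, gen) == 0
            rec, scale2 = T.path_distance_matrix(tree)
            np.testing.assert_allclose(
                rec.values * scale2, dm.values, atol=1e-9
            )

    def test_matches_dendropy_nj_on_additive_input(self, rng):
        gen = synthetic.random_binary_tree(8, rng)
        dm, _ = T.path_distance_matrix(gen)
        mine = T.neighbor_joining(dm)
        csv = "," + ",".join(dm.labels) + "\n" + "\n".join(
            lab + "," + ",".join(map(str, row))
            for lab, row in zip(dm.labels, dm.values)
        )
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=","
        )
        ref = pdm.nj_tree()
        assert T.rf_distance(mine, ref) == 0

    def test_tie_breaks_lexicographically(self):
        # equidistant triple: every Q is tied; (A, B) must join first
        dm = DistanceMatrix(
            ("C", "A", "B", "D"),
            (np.ones((4, 4)) - np.eye(4)) * 0.5,
        )
        tree = T.neighbor_joining(dm)
        assert frozenset({"A", "B"}) in T.splits(tree) or frozenset(
            {"C", "D"}
        ) in T.splits(tree)
        # deterministic: identical call, identical newick
        assert T.write_newick(tree) == T.write_newick(T.neighbor_joining(dm))

    def test_clamp_flag(self):
        dm = DistanceMatrix(
            ("A", "B", "C", "D"),
            np.array([
                [0, 0.1, 0.5, 0.5],
                [0.1, 0, 0.12, 0.5],
                [0.5, 0.12, 0, 0.1],
                [0.5, 0.5, 0.1, 0],
            ]),
        )
        clamped = T.neighbor_joining(dm, clamp_negative=True)
        for edge in clamped.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


class TestFitch:
    def test_constant_and_single_split_columns(self):
        tree = T.parse_newick("((A,B),(C,D));")
        bm = binary_matrix(
            [[1, 1], [1, 1], [1, 0], [1, 0]], labels=list("ABCD")
        )
        assert T.fitch_score(tree, bm) == 1  # constant col 0, one change col 1

    def test_matches_bruteforce_on_random_trees(self, rng):
        for _ in range(30):
            n = 6
            labels = [f"L{i}" for i in range(n)]
            adj = {n: [0, 1, 2], 0: [n], 1: [n], 2: [n]}
            nxt = n + 1
            for k in range(3, n):
                edges = sorted(
                    (u, v) for u in adj for v in adj[u] if u < v
                )
                u, v = edges[int(rng.integers(len(edges)))]
                T._insert_leaf(adj, k, nxt, u, v)
                nxt += 1
            values = rng.integers(0, 2, size=(n, 10)).astype(np.uint8)
            tree = T._adjacency_to_tree(adj, labels)
            bm = binary_matrix(values, labels)
            assert T.fitch_score(tree, bm) == brute_force_fitch(adj, values)

    def test_invariant_under_rerooting(self, rng):
        gen = synthetic.random_binary_tree(7, rng)
        labels = sorted(T.leaf_labels(gen))
        values = rng.integers(0, 2, size=(7, 12)).astype(np.uint8)
        bm = binary_matrix(values, labels)
        base = T.fitch_score(gen, bm)
        for lab in labels:
            rooted = T.root_at_outgroup(gen, lab)
            assert T.fitch_score(rooted, bm) == base
        # lower bound: at least one change per non-constant column
        nonconst = (values.min(axis=0) != values.max(axis=0)).sum()
        assert base >= nonconst

    def test_leaf_row_mismatch_errors(self):
        tree = T.parse_newick("((A,B),(C,E));")
        bm = binary_matrix([[0], [0], [1], [1]], labels=list("ABCD"))
        with pytest.raises(ValueError, match="differ"):
            T.fitch_score(tree, bm)


class TestParsimonySearch:
    def test_four_taxon_supported_split(self):
        bm = binary_matrix(
            [[1, 1, 0], [1, 1, 0], [0, 0, 1], [0, 0, 1]],
            labels=list("ABCD"),
        )
        res = T.parsimony_search(bm)
        assert res.score == 3  # one change per column
        assert frozenset({"C", "D"}) in T.splits(res.tree) or frozenset(
            {"A", "B"}
        ) in T.splits(res.tree)

    def test_exhaustive_equals_enumeration_minimum(self, rng):
        for _ in range(5):
            values = rng.integers(0, 2, size=(6, 10)).astype(np.uint8)
            bm = binary_matrix(values)
            res = T.parsimony_search(bm)
            assert res.method == "exhaustive"
            labels = sorted(bm.row_labels)
            pat, w = T._compress_columns(values)
            states = T._leaf_states(pat)
            scores = [
                T._score_adjacency(adj, states, w)
                for adj in T._enumerate_topologies(6)
            ]
            assert len(scores) == 105
            assert res.score == min(scores)

    def test_constant_matrix_degenerate(self):
        bm = binary_matrix(np.ones((5, 4)))
        with pytest.warns(UserWarning, match="no variable columns"):
            res = T.parsimony_search(bm)
        assert res.score == 0
        assert res.method == "degenerate"
        assert T.leaf_labels(res.tree) == frozenset(bm.row_labels)

    def test_heuristic_deterministic_given_seed(self, rng):
        values = rng.integers(0, 2, size=(11, 30)).astype(np.uint8)
        bm = binary_matrix(values)
        r1 = T.parsimony_search(bm, seed=5)
        r2 = T.parsimony_search(bm, seed=5)
        assert r1.method == "stepwise+nni"
        assert r1.score == r2.score
        assert T.canonical_newick(r1.tree) == T.canonical_newick(r2.tree)

    def test_heuristic_finds_exhaustive_optimum_small(self, rng):
        values = rng.integers(0, 2, size=(7, 12)).astype(np.uint8)
        bm = binary_matrix(values)
        exact = T.parsimony_search(bm)
        heur = T.parsimony_search(bm, exhaustive_limit=3, seed=1)
        assert heur.score == exact.score


class TestRootingAndComparison:
    def test_root_at_outgroup(self):
        tree = T.parse_newick("((A:1,B:1):1,(C:1,D:4):1);")
        rooted = T.root_at_outgroup(tree, "D")
        kids = rooted.seed_node.child_nodes()
        assert any(
            ch.is_leaf() and ch.taxon.label == "D" and ch.edge.length == 2.0
            for ch in kids
        )
        with pytest.raises(ValueError, match="Z"):
            T.root_at_outgroup(tree, "Z")

    def test_rf_unchanged_by_rooting(self, rng):
        t1 = synthetic.random_binary_tree(8, rng)
        t2 = synthetic.random_binary_tree(8, rng)
        base = T.rf_distance(t1, t2)
        assert T.rf_distance(T.root_at_outgroup(t1, "T000"), t2) == base
        assert T.rf_distance(t1, T.root_at_outgroup(t2, "T003")) == base

    def test_rf_worked_examples_and_symmetry(self):
        a = T.parse_newick("((A,B),(C,D));")
        b = T.parse_newick("((A,C),(B,D));")
        assert T.rf_distance(a, a) == 0
        assert T.rf_distance(a, b) == T.rf_distance(b, a) == 2

    def test_rf_matches_dendropy(self, rng):
        for _ in range(10):
            tns = dendropy.TaxonNamespace()
            t1 = synthetic.random_binary_tree(10, rng)
            t2 = synthetic.random_binary_tree(10, rng)
            d1 = dendropy.Tree.get(
                data=T.write_newick(t1) + ";", schema="newick",
                taxon_namespace=tns,
            )
            d2 = dendropy.Tree.get(
                data=T.write_newick(t2) + ";", schema="newick",
                taxon_namespace=tns,
            )
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            assert T.rf_distance(t1, t2) == treecompare.symmetric_difference(
                d1, d2
            )


class TestConsensus:
    def test_identical_trees_full_support(self):
        trees = [T.parse_newick("((A,B),(C,D),E);") for _ in range(3)]
        cons = T.majority_rule_consensus(trees)
        assert T.rf_distance(cons, trees[0]) == 0
        labels = {
            nd.label
            for nd in cons.preorder_node_iter()
            if not nd.is_leaf() and nd.label
        }
        assert labels == {"100.0"}

    def test_two_of_three_support(self):
        trees = [
            T.parse_newick("((A,B),(C,D),E);"),
            T.parse_newick("((A,B),(C,E),D);"),
            T.parse_newick("((A,B),(C,D),E);"),
        ]
        cons = T.majority_rule_consensus(trees)
        freqs = T.split_frequencies(trees)
        assert freqs[frozenset({"C", "D"})] == pytest.approx(200 / 3)
        labels = {
            nd.label
            for nd in cons.preorder_node_iter()
            if not nd.is_leaf() and nd.label
        }
        assert labels == {"100.0", "66.7"}

    def test_exact_half_excluded(self):
        trees = [
            T.parse_newick("((A,B),(C,D),E);"),
            T.parse_newick("((A,C),(B,D),E);"),
        ]
        cons = T.majority_rule_consensus(trees)
        assert T.splits(cons) == frozenset()  # star: no split above 50%

    def test_annotated_full_tree_carries_frequencies(self):
        full = T.parse_newick("((A,B),(C,D),E);")
        trees = [full, T.parse_newick("((A,B),(C,E),D);")]
        freqs = T.split_frequencies(trees)
        annotated = T.annotate_supports(full, freqs)
        labels = {
            nd.label
            for nd in annotated.preorder_node_iter()
            if not nd.is_leaf() and nd.label
        }
        assert labels == {"100.0", "50.0"}

    def test_leaf_set_mismatch_errors(self):
        with pytest.raises(ValueError):
            T.split_frequencies([
                T.parse_newick("((A,B),(C,D));"),
                T.parse_newick("((A,B),(C,E));"),
            ])


class TestRestrictContract:
    def test_prune_one_leaf_gives_star(self):
        tree = T.parse_newick("((A,B),(C,D));")
        pruned = T.restrict_to_taxa(tree, {"A", "B", "C"})
        assert T.leaf_labels(pruned) == {"A", "B", "C"}
        assert T.splits(pruned) == frozenset()

    def test_prune_to_two_taxa(self):
        tree = T.parse_newick("((A:1,B:2):1,(C:3,D:4):1);")
        pruned = T.restrict_to_taxa(tree, {"A", "D"})
        assert T.leaf_labels(pruned) == {"A", "D"}

    def test_contract_monophyletic_group(self):
        tree = T.parse_newick("(((B73,Mo17),(W22,PH207)),(X,(Y,Z)));")
        contracted = T.contract_groups(
            tree, {"Zea_mays": {"B73", "Mo17", "W22", "PH207"}}
        )
        assert T.leaf_labels(contracted) == {"Zea_mays", "X", "Y", "Z"}

    def test_contract_non_monophyletic_errors(self):
        tree = T.parse_newick("((A,C),(B,D),E);")
        with pytest.raises(ValueError, match="grp"):
            T.contract_groups(tree, {"grp": {"A", "B"}})

    def test_unknown_taxa_rejected(self):
        tree = T.parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            T.restrict_to_taxa(tree, {"A", "Q"})


class TestNewick:
    def test_roundtrip_canonical(self):
        tree = T.parse_newick("((A,B),(C,D));")
        again = T.parse_newick(T.write_newick(tree) + ";")
        assert T.canonical_newick(tree) == T.canonical_newick(again)

    def test_lengths_and_supports_roundtrip(self):
        text = "((A:1.0,B:2.0)90:1.0,C:3.0);"
        tree = T.parse_newick(text)
        internal = [
            nd for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd.label
        ]
        assert internal[0].label == "90"
        again = T.parse_newick(T.write_newick(tree) + ";")
        lengths = sorted(
            lf.edge.length for lf in again.leaf_node_iter()
        )
        assert lengths == pytest.approx([1.0, 2.0, 3.0], abs=1e-9)

    def test_malformed_input_errors(self):
        with pytest.raises(ValueError):
            T.parse_newick("((A,B);")
        with pytest.raises(ValueError):
            T.parse_newick("((A,A),B);")
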