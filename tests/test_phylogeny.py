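import itertools

import numpy as np
import pytest

from phylospot import Phylogeny, TreeError, bladj_smooth, clade_ranges, faith_pd
from phylospot.synthetic import generate_phylogeny

from conftest import make_matrix, random_instance
from oracle_bruteforce import brute_pd


class TestNewickIO:
    @pytest.mark.parametrize(
        "newick, n_leaves, n_internal",
        [
            ("((A:1,B:1):1,C:2);", 3, 2),
            ("(A:1);", 1, 1),
            ("(A:1,B:1,C:1);", 3, 1),  # polytomies are kept as-is
        ],
    )
    def test_parse(self, newick, n_leaves, n_internal):
        t = Phylogeny.from_newick_string(newick)
        assert t.n_leaves == n_leaves
        internal = sum(1 for n in t.tree.preorder_node_iter() if not n.is_leaf())
        assert internal == n_internal

    def test_roundtrip_preserves_lengths_and_topology(self):
        t = generate_phylogeny(20, seed=7)
        t2 = Phylogeny.from_newick_string(t.to_newick())
        assert sorted(t2.leaf_labels) == sorted(t.leaf_labels)
        assert t2.total_branch_length == pytest.approx(t.total_branch_length, abs=1e-9)
        d1, d2 = t.leaf_depths(), t2.leaf_depths()
        for label in d1:
            assert d2[label] == pytest.approx(d1[label], abs=1e-9)

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(TreeError):
            Phylogeny.from_newick_string("((A:1,B:1:1,C:2);")

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(TreeError):
            Phylogeny.from_newick_string("((A:1,A:1):1,C:2);")


class TestFaithPD:
    def test_worked_examples(self, worked_tree):
        assert faith_pd(worked_tree, ["A", "B"]) == pytest.approx(3.0)
        assert faith_pd(worked_tree, ["A", "B", "C"]) == pytest.approx(5.0)

    def test_single_taxon_rooted_is_root_path(self, worked_tree):
        assert faith_pd(worked_tree, ["A"]) == pytest.approx(2.0)
        assert faith_pd(worked_tree, ["C"]) == pytest.approx(2.0)

    def test_unrooted_variant(self, worked_tree):
        # spanning path A-B excludes the stem below their ancestor
        assert faith_pd(worked_tree, ["A", "B"], rooted=False) == pytest.approx(2.0)
        assert faith_pd(worked_tree, ["A"], rooted=False) == 0.0

    def test_all_subsets_match_bruteforce(self):
        """All 255 non-empty subsets of an 8-leaf Yule tree, both rootings."""
        tree = generate_phylogeny(8, seed=11)
        leaves = tree.leaf_labels
        for r in range(1, 9):
            for taxa in itertools.combinations(leaves, r):
                for rooted in (True, False):
                    assert faith_pd(tree, list(taxa), rooted=rooted) == pytest.approx(
                        brute_pd(tree, list(taxa), rooted=rooted), abs=1e-9
                    )

    def test_monotone_in_taxa(self):
        tree = generate_phylogeny(12, seed=3)
        leaves = sorted(tree.leaf_labels)
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = int(rng.integers(1, 11))
            sub = list(rng.choice(leaves, size=k, replace=False))
            extra = next(l for l in leaves if l not in sub)
            assert faith_pd(tree, sub) <= faith_pd(tree, sub + [extra]) + 1e-12

    def test_full_leaf_set_equals_total_branch_length(self):
        tree = generate_phylogeny(15, seed=5)
        assert faith_pd(tree, tree.leaf_labels) == pytest.approx(
            tree.total_branch_length, abs=1e-9
        )

    def test_errors(self, worked_tree):
        with pytest.raises(ValueError):
            faith_pd(worked_tree, [])
        with pytest.raises(ValueError):
            faith_pd(worked_tree, ["A", "Z"])


class TestCladeRanges:
    def test_leaf_and_sister_union(self):
        tree = Phylogeny.from_newick_string("((A:1,B:1):1,C:2);")
        matrix = make_matrix({"A": ["c1", "c2"], "B": ["c1", "c2"], "C": ["c3"]})
        idx = clade_ranges(tree, matrix)
        assert idx.range_for_leaf("A") == 2
        assert idx.range_for_leaf("C") == 1
        # sister species with identical ranges: parent branch union is the same
        parent_rows = [i for i in range(len(idx.ranges))
                       if i not in idx.leaf_branch.values()]
        assert any(idx.ranges[i] == 2 for i in parent_rows)

    def test_matches_bruteforce_unions(self):
        rng = np.random.default_rng(42)
        tree, matrix = random_instance(rng, max_species=10, max_cells=20)
        idx = clade_ranges(tree, matrix)
        occupied = {
            s: set(np.nonzero(matrix.incidence[i])[0])
            for i, s in enumerate(matrix.species)
        }
        for node in tree.tree.postorder_node_iter():
            union = set()
            for leaf in node.leaf_iter():
                union |= occupied[leaf.taxon.label]
            if node.is_leaf():
                assert idx.range_for_leaf(node.taxon.label) == len(union)

    def test_rootward_monotone(self):
        rng = np.random.default_rng(1)
        tree, matrix = random_instance(rng)
        idx = clade_ranges(tree, matrix)
        nodes = list(tree.tree.postorder_node_iter())
        row = {}
        k = 0
        for n in nodes:  # reconstruct row order of kept branches
            union = any(
                matrix.incidence[matrix.species.get_loc(lf.taxon.label)].any()
                for lf in n.leaf_iter()
            )
            if union:
                row[id(n)] = k
                k += 1
        for n in nodes:
            if n.parent_node is not None and id(n) in row and id(n.parent_node) in row:
                assert idx.ranges[row[id(n)]] <= idx.ranges[row[id(n.parent_node)]]


class TestBladjSmooth:
    def test_single_unfixed_node_is_midpoint(self):
        t = Phylogeny.from_newick_string("((A:1)X:1)R;")
        out = bladj_smooth(t, {"R": 12.0})
        # R(12) -> X(6) -> A(0): branches 6 and 6
        lengths = sorted(e.length for e in out.tree.preorder_edge_iter()
                         if e.length is not None)
        assert lengths == pytest.approx([6.0, 6.0])

    def test_two_unfixed_nodes_spaced_in_thirds(self):
        t = Phylogeny.from_newick_string("(((A:1)Y:1)X:1)R;")
        out = bladj_smooth(t, {"R": 12.0})
        lengths = [e.length for e in out.tree.preorder_edge_iter()
                   if e.length is not None]
        assert lengths == pytest.approx([4.0, 4.0, 4.0])

    def test_all_internal_fixed_is_identity_on_ages(self):
        t = Phylogeny.from_newick_string("((A:1,B:1)X:1,C:2)R;")
        out = bladj_smooth(t, {"R": 10.0, "X": 4.0})
        depths = out.leaf_depths()
        assert all(d == pytest.approx(10.0) for d in depths.values())
        x = next(n for n in out.tree.preorder_node_iter() if n.label == "X")
        assert x.edge.length == pytest.approx(6.0)
        assert all(ch.edge.length == pytest.approx(4.0) for ch in x.child_nodes())

    def test_root_must_be_constrained(self):
        t = Phylogeny.from_newick_string("((A:1,B:1)X:1,C:2)R;")
        with pytest.raises(TreeError):
            bladj_smooth(t, {"X": 4.0})

    def test_inconsistent_constraint_rejected(self):
        t = Phylogeny.from_newick_string("((A:1,B:1)X:1,C:2)R;")
        with pytest.raises(TreeError):
            bladj_smooth(t, {"R": 5.0, "X": 9.0})

    def test_ultrametric_on_random_topology(self):
        tree = generate_phylogeny(16, seed=9)
        root = tree.tree.seed_node
        root.label = "root"
        out = bladj_smooth(tree, {"root": 100.0})
        assert out.is_ultrametric(tol=1e-9)
        assert max(out.leaf_depths().values()) == pytest.approx(100.0)
        assert all((e.length or 0) >= 0 for e in out.tree.preorder_edge_iter())
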