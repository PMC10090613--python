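import itertools

import numpy as np
import pytest

from bivesdelim.distance import DistanceMatrix
from bivesdelim.phylo import (PhyloError, bootstrap_support, edge_bipartitions,
                              is_bipartition_clade, neighbor_joining,
                              parse_newick, reciprocal_monophyly, tree_to_dict,
                              write_newick)
from conftest import make_alignment, random_additive_tree


def dm_from(labels, rows):
    values = np.array(rows, dtype=float)
    n = len(labels)
    return DistanceMatrix(tuple(labels), values,
                          np.full((n, n), 1000, dtype=np.int64))


def patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    out = {}
    for a, b in itertools.combinations(labels, 2):
        ta = tree.taxon_namespace.get_taxon(a)
        tb = tree.taxon_namespace.get_taxon(b)
        out[(a, b)] = pdm.patristic_distance(ta, tb)
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = dm_from("ABC", [[0, 5, 9], [5, 0, 10], [9, 10, 0]])
        tree = neighbor_joining(dm)
        dists = patristic(tree)
        # a = (dAB + dAC - dBC)/2 = 2, b = 3, c = 7
        assert dists[("A", "B")] == pytest.approx(5)
        assert dists[("A", "C")] == pytest.approx(9)
        assert dists[("B", "C")] == pytest.approx(10)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # generating tree ((A:2,B:3):1,(C:2,D:2))
        dm = dm_from("ABCD", [[0, 5, 5, 5], [5, 0, 6, 6],
                              [5, 6, 0, 4], [5, 6, 4, 0]])
        tree = neighbor_joining(dm)
        assert edge_bipartitions(tree) == {frozenset({"A", "B"})}
        dists = patristic(tree)
        for (a, b), expect in {("A", "B"): 5, ("A", "C"): 5, ("A", "D"): 5,
                               ("B", "C"): 6, ("B", "D"): 6, ("C", "D"): 4}.items():
            assert dists[(a, b)] == pytest.approx(expect)

    def test_equal_distances_resolved_deterministically(self):
        dm = dm_from("ABCD", (np.ones((4, 4)) - np.eye(4)).tolist())
        t1 = write_newick(neighbor_joining(dm))
        t2 = write_newick(neighbor_joining(dm))
        assert t1 == t2

    def test_fewer_than_three_labels_errors(self):
        dm = dm_from("AB", [[0, 1], [1, 0]])
        with pytest.raises(PhyloError):
            neighbor_joining(dm)

    def test_undefined_distance_errors_listing_pair(self):
        values = np.array([[0, np.nan, 2], [np.nan, 0, 3], [2, 3, 0]])
        dm = DistanceMatrix(("A", "B", "C"), values,
                            np.full((3, 3), 10, dtype=np.int64))
        with pytest.raises(PhyloError, match="'A', 'B'"):
            neighbor_joining(dm)

    @pytest.mark.parametrize("seed", range(40))
    def test_additive_matrices_recover_generating_topology(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        newick, dm = random_additive_tree(rng, n)
        truth = parse_newick(newick)
        tree = neighbor_joining(dm)
        assert edge_bipartitions(tree) == edge_bipartitions(truth)
        # branch lengths: patristic distances reproduce the input matrix
        dists = patristic(tree)
        for (a, b), d in dists.items():
            assert d == pytest.approx(dm.get(a, b), abs=1e-6)

    def test_total_length_invariant_under_label_permutation(self):
        rng = np.random.default_rng(1)
        _, dm = random_additive_tree(rng, 8)
        total = sum(e.length for e in neighbor_joining(dm).preorder_edge_iter()
                    if e.length)
        perm = list(rng.permutation(len(dm.labels)))
        labels = tuple(dm.labels[i] for i in perm)
        dm2 = DistanceMatrix(labels, dm.values[np.ix_(perm, perm)],
                             dm.comparable_sites[np.ix_(perm, perm)])
        total2 = sum(e.length for e in neighbor_joining(dm2).preorder_edge_iter()
                     if e.length)
        assert total2 == pytest.approx(total)

    def test_agrees_with_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            _, dm = random_additive_tree(rng, int(rng.integers(4, 10)))
            ours = edge_bipartitions(neighbor_joining(dm))
            sym = (dm.values + dm.values.T) / 2  # exact symmetry for skbio
            sk_dm = skbio.DistanceMatrix(sym, ids=list(dm.labels))
            sk_tree = skbio_nj(sk_dm)
            theirs = edge_bipartitions(
                parse_newick(str(sk_tree).strip()))
            assert ours == theirs


class TestBootstrap:
    def make_two_group_alignment(self):
        """Two 4-taxon groups differing at 40 of 80 columns."""
        block_a = "A" * 40
        block_b = "C" * 40
        shared = "G" * 40
        rows = {f"a{i}": shared + block_a for i in range(2)}
        rows.update({f"b{i}": shared + block_b for i in range(2)})
        return make_alignment(rows)

    def test_clear_split_has_near_certain_support(self):
        aln = self.make_two_group_alignment()
        tree = bootstrap_support(aln, replicates=200, seed=0)
        supports = tree_to_dict(tree)["supports"]
        key = "|".join(sorted(["a0", "a1"]))
        assert supports[key] >= 99

    def test_single_replicate_supports_are_zero_or_hundred(self):
        aln = self.make_two_group_alignment()
        tree = bootstrap_support(aln, replicates=1, seed=3)
        supports = tree_to_dict(tree)["supports"]
        assert set(supports.values()) <= {0.0, 100.0}

    def test_same_seed_identical_supports(self):
        aln = self.make_two_group_alignment()
        s1 = tree_to_dict(bootstrap_support(aln, replicates=50, seed=7))["supports"]
        s2 = tree_to_dict(bootstrap_support(aln, replicates=50, seed=7))["supports"]
        assert s1 == s2


class TestBipartitions:
    def test_explicit_bipartition_present(self):
        tree = parse_newick("((A,B),(C,D));")
        assert is_bipartition_clade(tree, {"A", "B"})

    def test_absent_bipartition(self):
        tree = parse_newick("((A,B),(C,D));")
        assert not is_bipartition_clade(tree, {"A", "C"})

    def test_singleton_is_always_a_clade(self):
        tree = parse_newick("((A,B),(C,D));")
        assert is_bipartition_clade(tree, {"A"})

    def test_unknown_tip_errors(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(PhyloError):
            is_bipartition_clade(tree, {"A", "Z"})


class TestReciprocalMonophyly:
    def test_clean_split_true(self):
        tree = parse_newick("((A1,A2),(B1,B2));")
        assert reciprocal_monophyly(tree, {"A1", "A2"}, {"B1", "B2"})

    def test_interleaved_false(self):
        tree = parse_newick("((A1,B1),(A2,B2));")
        assert not reciprocal_monophyly(tree, {"A1", "A2"}, {"B1", "B2"})

    def test_restriction_ignores_excluded_taxa(self):
        tree = parse_newick("((A1,A2),X,(B1,B2));")
        assert reciprocal_monophyly(tree, {"A1", "A2"}, {"B1", "B2"})

    def test_overlapping_groups_error(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(PhyloError):
            reciprocal_monophyly(tree, {"A", "B"}, {"B", "C"})


class TestNewick:
    def test_roundtrip_lengths_and_topology(self):
        text = "((A:1,B:2):0.5,C:3);"
        tree = parse_newick(text)
        back = parse_newick(write_newick(tree))
        assert edge_bipartitions(back, include_trivial=True) == \
            edge_bipartitions(tree, include_trivial=True)
        assert patristic(back) == patristic(tree)

    def test_supports_preserved(self):
        tree = parse_newick("((A,B)95:0.5,(C,D)87:0.2);")
        supports = sorted(
            node.support for node in tree.preorder_node_iter()
            if getattr(node, "support", None) is not None)
        assert supports == [87.0, 95.0]
        assert "95" in write_newick(tree)

    def test_unbalanced_parentheses_error(self):
        with pytest.raises(PhyloError):
            parse_newick("((A,B);")

    def test_duplicate_labels_error(self):
        with pytest.raises(PhyloError):
            parse_newick("((A,B),(A,C));")
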