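"""Neighbor joining, bootstrap, rooting and lineage assignment."""
import numpy as np
import pytest

from refugia.njtree import (
    assign_lineages,
    bootstrap_support,
    flag_introgression,
    nj_tree,
    root_with_outgroup,
    tree_bipartitions,
)
from refugia.sequences import collapse_haplotypes, distance_matrix
from tests.oracles import random_additive_tree


def edge_lengths(tree):
    return {
        leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
    }


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(d, labels)
        lens = edge_lengths(tree)
        assert lens["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lens["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lens["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:1)); internal edge length 1
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
        )
        tree = nj_tree(d, labels)
        assert tree_bipartitions(tree) == {frozenset({"C", "D"})}
        lens = edge_lengths(tree)
        assert lens == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 1})
        internal = [
            e.length
            for e in tree.preorder_edge_iter()
            if e.head_node.is_internal() and e.tail_node is not None
        ]
        assert internal == pytest.approx([1.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_random_additive_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 9))
        d, labels, true_splits = random_additive_tree(n, rng)
        tree = nj_tree(d, labels)
        assert tree_bipartitions(tree) == true_splits

    def test_label_order_invariance(self):
        rng = np.random.default_rng(42)
        d, labels, _ = random_additive_tree(7, rng)
        perm = rng.permutation(len(labels))
        d2 = d[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        assert tree_bipartitions(nj_tree(d, labels)) == tree_bipartitions(nj_tree(d2, labels2))

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d, ["A", "B", "C"])

    def test_negative_branch_estimates_clamped(self):
        # a non-additive matrix known to produce a negative NJ branch estimate
        d = np.array(
            [[0, 2, 2, 2], [2, 0, 2, 0.1], [2, 2, 0, 2], [2, 0.1, 2, 0]], dtype=float
        )
        tree = nj_tree(d, ["A", "B", "C", "D"])
        assert all((e.length or 0) >= 0 for e in tree.preorder_edge_iter())


class TestBootstrap:
    def test_invariant_columns_give_full_support(self):
        # every site carries the same pattern, so every resample rebuilds the
        # same tree: all reference splits get 100% support
        seqs = ["A" * 30, "C" * 30, "G" * 30, "T" * 30]
        labels = ["w", "x", "y", "z"]
        d, _ = distance_matrix(seqs, labels)
        tree = nj_tree(d, labels)
        support = bootstrap_support(seqs, labels, tree, n_replicates=10, seed=0)
        assert all(v == 100.0 for v in support.values())

    def test_deep_split_strongly_supported(self, rng):
        base = rng.choice(list("ACGT"), size=200)
        other = base.copy()
        other[:50] = np.where(other[:50] == "A", "C", "A")  # 50 fixed differences
        group1 = ["".join(base), "".join(base)]
        group2 = ["".join(other), "".join(other)]
        seqs = group1 + group2
        # mutate one site in each copy so all four are distinct
        seqs[1] = "G" + seqs[1][1:]
        seqs[3] = "G" + seqs[3][1:]
        labels = ["a1", "a2", "b1", "b2"]
        d, _ = distance_matrix(seqs, labels)
        tree = nj_tree(d, labels)
        support = bootstrap_support(seqs, labels, tree, n_replicates=100, seed=1)
        split = frozenset({"b1", "b2"})
        assert support[split] >= 99.0

    def test_deterministic_under_seed(self):
        seqs = ["ACGTACGTAA", "ACGTACGTAC", "TTTTACGTAA", "TTTAACGTAA"]
        labels = list("abcd")
        d, _ = distance_matrix(seqs, labels)
        tree = nj_tree(d, labels)
        s1 = bootstrap_support(seqs, labels, tree, n_replicates=50, seed=9)
        s2 = bootstrap_support(seqs, labels, tree, n_replicates=50, seed=9)
        assert s1 == s2


class TestRooting:
    def test_three_leaf_root_separates_outgroup(self):
        d = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], dtype=float)
        tree = nj_tree(d, ["A", "B", "C"])
        rooted = root_with_outgroup(tree, "C")
        children = rooted.seed_node.child_nodes()
        leafsets = [frozenset(l.taxon.label for l in ch.leaf_iter()) for ch in children]
        assert frozenset({"C"}) in leafsets
        assert frozenset({"A", "B"}) in leafsets

    def test_rerooting_is_idempotent(self):
        rng = np.random.default_rng(3)
        d, labels, _ = random_additive_tree(6, rng)
        t1 = root_with_outgroup(nj_tree(d, labels), labels[0])
        t2 = root_with_outgroup(t1, labels[0])
        assert tree_bipartitions(t1) == tree_bipartitions(t2)

    def test_missing_outgroup_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="nope"):
            root_with_outgroup(nj_tree(d, ["A", "B", "C"]), "nope")


def _hapset_from(records):
    """records: list of (individual, species, sequence)."""
    from refugia.sequences import Alignment

    aln = Alignment(
        individuals=[r[0] for r in records],
        populations=[r[0].split("_")[0] for r in records],
        species=[r[1] for r in records],
        sequences=[r[2] for r in records],
    )
    return aln, collapse_haplotypes(aln)


class TestLineageAssignment:
    A1 = "A" * 40
    A2 = "A" * 39 + "C"
    B1 = "T" * 40
    B2 = "T" * 39 + "G"
    OUT = "G" * 20 + "C" * 20

    def _tree(self, hs, extra=()):
        labels = hs.haplotype_ids + ["OUT"]
        seqs = hs.sequences + [self.OUT]
        d, labels = distance_matrix(seqs, labels)
        return root_with_outgroup(nj_tree(d, labels), "OUT"), (d, labels)

    def test_clean_species_clades(self):
        aln, hs = _hapset_from(
            [("a_1", "spA", self.A1), ("a_2", "spA", self.A2),
             ("b_1", "spB", self.B1), ("b_2", "spB", self.B2)]
        )
        rooted, dist = self._tree(hs)
        lineages, report = assign_lineages(
            rooted, hs, dict(zip(aln.individuals, aln.species)), outgroup="OUT", distances=dist
        )
        hap_of = hs.haplotype_of()
        assert lineages[hap_of["a_1"]] == "spA"
        assert lineages[hap_of["b_2"]] == "spB"
        assert report["monophyletic"]

    def test_introgressed_haplotype_assigned_to_donor_lineage(self):
        # one spA individual carries a spB haplotype (shared, mixed carriers)
        aln, hs = _hapset_from(
            [("a_1", "spA", self.A1), ("a_2", "spA", self.A2), ("a_3", "spA", self.B1),
             ("b_1", "spB", self.B1), ("b_2", "spB", self.B2)]
        )
        rooted, dist = self._tree(hs)
        lineages, _ = assign_lineages(
            rooted, hs, dict(zip(aln.individuals, aln.species)), outgroup="OUT", distances=dist
        )
        shared = hs.haplotype_of()["a_3"]
        assert lineages[shared] == "spB"

    def test_single_species_trivially_monophyletic(self):
        aln, hs = _hapset_from(
            [("a_1", "spA", self.A1), ("a_2", "spA", self.A2),
             ("a_3", "spA", "A" * 38 + "CC")]
        )
        rooted, dist = self._tree(hs)
        lineages, report = assign_lineages(
            rooted, hs, dict(zip(aln.individuals, aln.species)), outgroup="OUT", distances=dist
        )
        assert set(lineages.values()) == {"spA"}
        assert report["monophyletic"]


class TestFlagging:
    def test_mixed_population_classes(self):
        aln, hs = _hapset_from(
            [("p1_1", "spA", "A" * 30), ("p1_2", "spA", "T" * 30),
             ("p2_1", "spB", "T" * 30)]
        )
        # lineage map: the A-haplotype is spA, the T-haplotype is spB
        hap_of = hs.haplotype_of()
        lineages = {hap_of["p1_1"]: "spA", hap_of["p2_1"]: "spB"}
        flags, classes = flag_introgression(
            hs,
            lineages,
            dict(zip(aln.individuals, aln.species)),
            dict(zip(aln.individuals, aln.populations)),
        )
        status = dict(zip(flags.individual, flags.status))
        assert status["p1_2"] == "introgressed" and status["p1_1"] == "original"
        assert classes["p1"] == "mixed"
        assert classes["p2"] == "original"

    def test_no_flags_without_introgression(self, small_system):
        truth, aln_df, _, _ = small_system
        # zero-introgression rerun of the same system
        from refugia import synthetic as syn
        from refugia.sequences import Alignment

        aln2, _ = syn.simulate_sequences(truth, introgression_prob=0.0, seed=5)
        aln = Alignment.from_frame(aln2)
        hs = collapse_haplotypes(aln)
        labels = hs.haplotype_ids + ["OUT"]
        seqs = hs.sequences + [truth.outgroup_sequence]
        d, labels = distance_matrix(seqs, labels)
        rooted = root_with_outgroup(nj_tree(d, labels), "OUT")
        indsp = dict(zip(aln.individuals, aln.species))
        lineages, _ = assign_lineages(rooted, hs, indsp, outgroup="OUT", distances=(d, labels))
        flags, _ = flag_introgression(
            hs, lineages, indsp, dict(zip(aln.individuals, aln.populations))
        )
        assert (flags.status == "original").all()
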