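"""Bipartition algebra, consensus methods, and internode certainty."""

import itertools

import numpy as np
import pytest

from phylodiscord.consensus import (Bipartition, annotate_consensus_with_ic,
                                    bipartition_frequencies, bipartition_set,
                                    internode_certainty,
                                    majority_rule_consensus,
                                    semistrict_consensus, strict_consensus,
                                    tree_from_splits)
from phylodiscord.parsimony import enumerate_unrooted_topologies
from phylodiscord.treeio import TreeSampleSet, parse_newick

from conftest import edge_cut_splits, random_tree, splitset

UNIVERSE6 = tuple("ABCDEF")


def pop_of(trees, tag=""):
    return TreeSampleSet([t.copy() for t in trees], genome_tag=tag)


class TestBipartition:
    def test_canonical_equality_is_mask_equality(self):
        a = Bipartition.from_side(UNIVERSE6, {"A", "B"})
        b = Bipartition.from_side(UNIVERSE6, {"C", "D", "E", "F"})
        assert a == b and hash(a) == hash(b)

    def test_compatibility_four_point_rule(self):
        ab = Bipartition.from_side(UNIVERSE6, {"A", "B"})
        ac = Bipartition.from_side(UNIVERSE6, {"A", "C"})
        cd = Bipartition.from_side(UNIVERSE6, {"C", "D"})
        assert ab.conflicts_with(ac)
        assert ab.compatible_with(cd)

    def test_restriction_matches_mask_intersection(self):
        b = Bipartition.from_side(UNIVERSE6, {"B", "C", "D"})
        r = b.restrict({"A", "B", "C", "E"})
        assert r == Bipartition.from_side(("A", "B", "C", "E"), {"B", "C"})

    def test_quartet_split(self, quartet):
        assert bipartition_set(quartet) == {
            Bipartition.from_side(tuple("ABCD"), {"A", "B"})}

    def test_resolved_tree_has_n_minus_3_splits(self):
        tree = parse_newick("(((A,B),(C,D)),(E,F));")
        assert len(bipartition_set(tree)) == 3

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_edge_cut_enumeration(self, seed):
        tree = random_tree(8, np.random.default_rng(seed))
        assert splitset(tree) == edge_cut_splits(tree)

    def test_small_trees_have_no_splits(self):
        assert bipartition_set(parse_newick("(A,B,C);")) == set()


class TestFrequencies:
    def test_simple_counting(self):
        trees = [parse_newick("((A,B),(C,D));")] * 3 + [parse_newick("((A,C),(B,D));")]
        table = bipartition_frequencies([pop_of(trees)])
        ab = Bipartition.from_side(tuple("ABCD"), {"A", "B"})
        assert table.frequency(ab) == pytest.approx(0.75)

    def test_equal_weight_pooling(self):
        t_ab = parse_newick("((A,B),C,D,E,F);")
        t_ac = parse_newick("((A,C),B,D,E,F);")
        table = bipartition_frequencies(
            [pop_of([t_ab] * 10), pop_of([t_ab] * 5 + [t_ac] * 5)])
        ab = Bipartition.from_side(UNIVERSE6, {"A", "B"})
        assert table.frequency(ab) == pytest.approx(0.75)

    def test_degenerate_weighting_equals_single_population(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        both = bipartition_frequencies([pop_of([t1]), pop_of([t2])],
                                       weights=[1.0, 0.0])
        single = bipartition_frequencies([pop_of([t1])])
        assert both.pooled == single.pooled

    def test_pooling_symmetry(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        fwd = bipartition_frequencies([pop_of([t1]), pop_of([t2])])
        rev = bipartition_frequencies([pop_of([t2]), pop_of([t1])])
        assert fwd.pooled == rev.pooled

    def test_mismatched_universes_rejected(self):
        from phylodiscord.treeio import TreeError

        with pytest.raises(TreeError, match="symmetric"):
            bipartition_frequencies([
                pop_of([parse_newick("((A,B),(C,D));")]),
                pop_of([parse_newick("((A,B),(C,E));")]),
            ])


def brute_force_mrc_splits(trees, threshold=0.5):
    """Split counting oracle: include splits above threshold, greedy at tie."""
    counts = {}
    for t in trees:
        for s in edge_cut_splits(t):
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    chosen = []
    for s, c in sorted(counts.items(),
                       key=lambda kv: (-kv[1], sorted(map(sorted, kv[0])))):
        freq = c / n
        if freq > threshold + 1e-12 or abs(freq - 0.5) <= 1e-12 <= abs(threshold - 0.5) + 1e-12:
            if abs(freq - 0.5) <= 1e-12 and abs(threshold - 0.5) > 1e-12:
                continue
            if all(_oracle_compatible(s, o) for o in chosen):
                chosen.append(s)
    return set(chosen)


def _oracle_compatible(s1, s2):
    for a in s1:
        for b in s2:
            if not (a & b) or a <= b or b <= a:
                return True
    return False


class TestConsensus:
    def test_identical_inputs_reproduce_topology(self):
        tree = parse_newick("(((A,B),(C,D)),(E,F));")
        table = bipartition_frequencies([pop_of([tree] * 5)])
        mrc = majority_rule_consensus(table)
        assert splitset(mrc) == splitset(tree)
        supports = [n.support for n in mrc.postorder()
                    if not n.is_leaf and n is not mrc.root and n.support]
        assert supports == pytest.approx([1.0] * 3)

    def test_sixty_forty_conflict_keeps_majority(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        table = bipartition_frequencies([pop_of([t1] * 3 + [t2] * 2)])
        mrc = majority_rule_consensus(table)
        assert splitset(mrc) == splitset(t1)
        node = [n for n in mrc.postorder()
                if not n.is_leaf and n is not mrc.root][0]
        assert node.support == pytest.approx(0.6)

    def test_uniform_five_leaf_population_is_star(self):
        trees = list(enumerate_unrooted_topologies(list("ABCDE")))
        assert len(trees) == 15
        table = bipartition_frequencies([pop_of(trees)])
        mrc = majority_rule_consensus(table)
        assert splitset(mrc) == set()

    @pytest.mark.parametrize("n_leaves,n_trees,seed", [
        (5, 8, 0), (5, 12, 1), (6, 10, 2), (6, 20, 3),
    ])
    def test_mrc_matches_split_counting_oracle(self, n_leaves, n_trees, seed):
        rng = np.random.default_rng(seed)
        pool = list(enumerate_unrooted_topologies([f"L{i}" for i in range(n_leaves)]))
        trees = [pool[i] for i in rng.integers(len(pool), size=n_trees)]
        table = bipartition_frequencies([pop_of(trees)])
        mrc = majority_rule_consensus(table)
        assert splitset(mrc) == brute_force_mrc_splits(trees)

    def test_strict_consensus_examples(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        assert splitset(strict_consensus([t1, t1])) == splitset(t1)
        assert splitset(strict_consensus([t1, t2])) == set()

    @pytest.mark.parametrize("seed", range(6))
    def test_strict_is_intersection_of_split_sets(self, seed):
        rng = np.random.default_rng(seed)
        t1, t2 = random_tree(7, rng), random_tree(7, rng)
        expected = edge_cut_splits(t1) & edge_cut_splits(t2)
        assert splitset(strict_consensus([t1, t2])) == expected

    def test_semistrict_keeps_compatible_union(self):
        t1 = parse_newick("((A,B),C,D,E);")
        t2 = parse_newick("(A,B,(C,D),E);")
        out = splitset(semistrict_consensus([t1, t2]))
        assert out == edge_cut_splits(t1) | edge_cut_splits(t2)

    def test_semistrict_conflicting_pair_is_star(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        assert splitset(semistrict_consensus([t1, t2])) == set()

    @pytest.mark.parametrize("seed", range(6))
    def test_semistrict_matches_compatibility_filter(self, seed):
        rng = np.random.default_rng(100 + seed)
        trees = [random_tree(6, rng) for _ in range(3)]
        per_tree = [edge_cut_splits(t) for t in trees]
        union = set().union(*per_tree)
        expected = {s for s in union
                    if all(_oracle_compatible(s, o)
                           for splits in per_tree for o in splits)}
        assert splitset(semistrict_consensus(trees)) == expected

    def test_mrc_contains_strict_consensus(self):
        rng = np.random.default_rng(7)
        trees = [random_tree(6, rng) for _ in range(6)]
        table = bipartition_frequencies([pop_of(trees)])
        mrc = splitset(majority_rule_consensus(table))
        strict = splitset(strict_consensus(trees))
        assert strict <= mrc

    def test_consensus_splits_pairwise_compatible(self):
        rng = np.random.default_rng(11)
        trees = [random_tree(8, rng) for _ in range(9)]
        table = bipartition_frequencies([pop_of(trees)])
        splits = list(bipartition_set(majority_rule_consensus(table)))
        for a, b in itertools.combinations(splits, 2):
            assert a.compatible_with(b)

    def test_threshold_validation(self):
        table = bipartition_frequencies([pop_of([parse_newick("((A,B),(C,D));")])])
        with pytest.raises(ValueError):
            majority_rule_consensus(table, threshold=0.4)


class TestTreeFromSplits:
    def test_incompatible_splits_rejected(self):
        from phylodiscord.treeio import TreeError

        ab = Bipartition.from_side(UNIVERSE6, {"A", "B"})
        ac = Bipartition.from_side(UNIVERSE6, {"A", "C"})
        with pytest.raises(TreeError):
            tree_from_splits(UNIVERSE6, [ab, ac])

    @pytest.mark.parametrize("seed", range(5))
    def test_reconstruction_round_trip(self, seed):
        tree = random_tree(9, np.random.default_rng(200 + seed))
        rebuilt = tree_from_splits(sorted(tree.leaf_labels()),
                                   list(bipartition_set(tree)))
        assert splitset(rebuilt) == splitset(tree)


class TestInternodeCertainty:
    def pooled_table(self, n2_ab=0):
        """Population 1 all supporting AB; population 2 split AB/AC."""
        t_ab = parse_newick("((A,B),C,D,E,F);")
        t_ac = parse_newick("((A,C),B,D,E,F);")
        pop1 = pop_of([t_ab] * 100, "cpDNA")
        pop2 = pop_of([t_ab] * n2_ab + [t_ac] * (100 - n2_ab), "nrITS")
        return bipartition_frequencies([pop1, pop2])

    def test_complete_conflict_gives_zero(self):
        table = self.pooled_table(n2_ab=0)
        ab = Bipartition.from_side(UNIVERSE6, {"A", "B"})
        assert internode_certainty(table, ab) == pytest.approx(0.0, abs=1e-12)

    def test_partial_conflict_reproduces_printed_value(self):
        # 100% in one genome, 50/50 in the other -> pooled 0.75 vs 0.25
        table = self.pooled_table(n2_ab=50)
        ab = Bipartition.from_side(UNIVERSE6, {"A", "B"})
        ic = internode_certainty(table, ab)
        assert ic == pytest.approx(0.1887, abs=5e-4)

    def test_no_conflict_gives_one(self):
        t = parse_newick("((A,B),C,D,E,F);")
        table = bipartition_frequencies([pop_of([t] * 10)])
        ab = Bipartition.from_side(UNIVERSE6, {"A", "B"})
        assert internode_certainty(table, ab) == 1.0

    def test_equal_prevalence_gives_zero_at_any_magnitude(self):
        t_ab = parse_newick("((A,B),C,D,E,F);")
        t_ac = parse_newick("((A,C),B,D,E,F);")
        star = parse_newick("(A,B,C,D,E,F);")
        table = bipartition_frequencies(
            [pop_of([t_ab, t_ac] + [star] * 8)])
        ab = Bipartition.from_side(UNIVERSE6, {"A", "B"})
        assert internode_certainty(table, ab) == pytest.approx(0.0, abs=1e-12)

    def test_unobserved_split_rejected(self):
        t = parse_newick("((A,B),C,D,E,F);")
        table = bipartition_frequencies([pop_of([t] * 4)])
        cd = Bipartition.from_side(UNIVERSE6, {"C", "D"})
        with pytest.raises(ValueError):
            internode_certainty(table, cd)

    def test_annotation_conflict_free_population(self):
        tree = parse_newick("(((A,B),(C,D)),(E,F));")
        table = bipartition_frequencies([pop_of([tree] * 5)])
        out = annotate_consensus_with_ic(majority_rule_consensus(table), table)
        ics = [n.ic for n in out.postorder()
               if not n.is_leaf and n is not out.root and n.ic is not None]
        assert ics == pytest.approx([1.0, 1.0, 1.0])

    def test_annotated_partial_conflict_edge(self):
        table = self.pooled_table(n2_ab=50)
        out = annotate_consensus_with_ic(majority_rule_consensus(table), table)
        ics = {n.ic for n in out.postorder()
               if not n.is_leaf and n is not out.root and n.ic is not None}
        assert any(abs(v - 0.1887) < 5e-4 for v in ics)

    @pytest.mark.parametrize("seed", range(4))
    def test_ic_bounded_on_random_pooled_populations(self, seed):
        rng = np.random.default_rng(300 + seed)
        pool = list(enumerate_unrooted_topologies(list("ABCDEF")))
        pops = [pop_of([pool[i] for i in rng.integers(len(pool), size=12)])
                for _ in range(2)]
        table = bipartition_frequencies(pops)
        for b in table.splits():
            if b.is_trivial() or table.frequency(b) <= 0:
                continue
            assert 0.0 <= internode_certainty(table, b) <= 1.0
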