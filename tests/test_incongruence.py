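"""Conflict detection, node displacement, classification, tanglegram."""

import numpy as np
import pytest

from phylodiscord.consensus import (bipartition_frequencies, bipartition_set,
                                    majority_rule_consensus)
from phylodiscord.incongruence import (CONGRUENT, HYBRIDISATION_CANDIDATE,
                                       ILS_CANDIDATE, attachment_context,
                                       build_taxon_map, calls_tsv,
                                       classify_species,
                                       collapse_accession_pair,
                                       node_displacement, prune_to_shared,
                                       supported_conflict, tanglegram_export)
from phylodiscord.simulate import (ScenarioConfig, generate_scenario,
                                   inject_capture, simulate_species_tree)
from phylodiscord.treeio import TreeError, TreeSampleSet, parse_newick

from conftest import random_tree, splitset


def annotated(newick: str, support: float = 1.0):
    """Parse a newick and give every internal edge the same support."""
    tree = parse_newick(newick)
    for node in tree.postorder():
        if not node.is_leaf and node is not tree.root:
            node.support = support
    return tree


class TestTaxonMap:
    def test_shared_species_intersection(self):
        rows = [("x1", "S1", "cpDNA"), ("x2", "S1", "nrITS"),
                ("y1", "S2", "cpDNA")]
        tmap = build_taxon_map(rows, {"x1", "y1"}, {"x2"})
        assert tmap.shared_species == {"S1"}

    def test_species_only_in_one_genome_excluded(self):
        rows = [("a", "S1", "cpDNA"), ("b", "S2", "cpDNA"),
                ("c", "S1", "nrITS")]
        tmap = build_taxon_map(rows, {"a", "b"}, {"c"})
        assert "S2" not in tmap.shared_species

    def test_conflicting_mapping_rejected(self):
        rows = [("a", "S1", "cpDNA"), ("a", "S2", "cpDNA")]
        with pytest.raises(ValueError, match="two species"):
            build_taxon_map(rows, {"a"}, set())

    def test_duplicate_rows_deduplicated(self):
        rows = [("a", "S1", "cpDNA")] * 3 + [("b", "S1", "nrITS")]
        tmap = build_taxon_map(rows, {"a"}, {"b"})
        assert tmap.accessions("S1", "cpDNA") == ["a"]

    def test_study_scale_overlap(self):
        # sampling shaped like the study: 67 cp taxa, 50 nuclear taxa
        cp_species = [f"S{i}" for i in range(67)]
        its_species = [f"S{i}" for i in range(17, 67)]
        rows = ([(f"c{i}", sp, "cpDNA") for i, sp in enumerate(cp_species)]
                + [(f"n{i}", sp, "nrITS") for i, sp in enumerate(its_species)])
        tmap = build_taxon_map(rows,
                               {f"c{i}" for i in range(67)},
                               {f"n{i}" for i in range(50)})
        assert len(tmap.shared_species) == 50


class TestPrune:
    def test_prune_to_triple(self, quartet):
        out = prune_to_shared(quartet, {"A", "C", "D"})
        assert out.leaf_labels() == {"A", "C", "D"}
        assert bipartition_set(out) == set()

    def test_prune_to_full_set_is_identity(self, quartet):
        out = prune_to_shared(quartet, {"A", "B", "C", "D"})
        assert splitset(out) == splitset(quartet)

    def test_too_small_keep_rejected(self, quartet):
        with pytest.raises(TreeError):
            prune_to_shared(quartet, {"A", "B"})

    @pytest.mark.parametrize("seed", range(6))
    def test_restriction_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(10, rng)
        labels = sorted(tree.leaf_labels())
        keep = set(labels[i] for i in rng.choice(len(labels), size=6,
                                                 replace=False))
        pruned = prune_to_shared(tree, keep)
        expected = {b.restrict(keep) for b in bipartition_set(tree)}
        expected = {b for b in expected if not b.is_trivial()}
        assert bipartition_set(pruned) == expected

    def test_lengths_summed_across_suppressed_nodes(self):
        tree = parse_newick("(((A:1,B:2):3,C:4):5,(D:6,E:7):8);")
        out = prune_to_shared(tree, {"A", "C", "D", "E"})
        a = out.find_leaf("A")
        assert a.length == pytest.approx(1 + 3)


class TestAttachmentContext:
    def test_quartet_shells(self, quartet):
        ctx = attachment_context(quartet, "A")
        assert [sorted(s) for s in ctx.shells] == [["B"], ["C", "D"]]

    def test_root_polytomy_single_shell(self):
        tree = parse_newick("(A,B,C,D);")
        ctx = attachment_context(tree, "A")
        assert len(ctx.shells) == 1
        assert ctx.shells[0] == {"B", "C", "D"}

    @pytest.mark.parametrize("seed", range(5))
    def test_shells_reconstruct_leaf_rooted_nesting(self, seed):
        tree = random_tree(9, np.random.default_rng(400 + seed))
        leaf = sorted(tree.leaf_labels())[seed % 9]
        ctx = attachment_context(tree, leaf)
        # shells are disjoint and together cover all other leaves
        union = set()
        for shell in ctx.shells:
            assert not (shell & union)
            union |= shell
        assert union == tree.leaf_labels() - {leaf}

    def test_missing_leaf_rejected(self, quartet):
        with pytest.raises(TreeError):
            attachment_context(quartet, "Z")


class TestNodeDisplacement:
    def test_identical_placement_is_zero(self):
        rng = np.random.default_rng(0)
        tree = random_tree(10, rng)
        for leaf in sorted(tree.leaf_labels())[:4]:
            assert node_displacement(tree, tree.copy(), leaf) == 0

    @pytest.mark.parametrize("target", [1, 2, 3])
    def test_constructed_regraft_distance(self, target):
        # a ladder tree offers regraft targets at every distance
        tree = parse_newick(
            "((((((A,B),(C,X)),(D,E)),(F,G)),(H,I)),(J,K));")
        derived, event = inject_capture(tree, "X", target, seed=1)
        assert event.displacement == target
        assert node_displacement(tree, derived, "X") == target

    def test_unaffected_by_relabelling_other_leaves(self):
        tree = parse_newick(
            "((((((A,B),(C,X)),(D,E)),(F,G)),(H,I)),(J,K));")
        derived, _ = inject_capture(tree, "X", 2, seed=1)
        d_before = node_displacement(tree, derived, "X")

        def relabel(t):
            out = t.copy()
            for leaf in out.leaves():
                if leaf.label != "X":
                    out.find_leaf(leaf.label).label = leaf.label.lower() * 2
            return out

        assert node_displacement(relabel(tree), relabel(derived), "X") == d_before

    def test_symmetric_in_tree_order(self):
        tree = parse_newick(
            "((((((A,B),(C,X)),(D,E)),(F,G)),(H,I)),(J,K));")
        derived, _ = inject_capture(tree, "X", 3, seed=2)
        assert (node_displacement(tree, derived, "X")
                == node_displacement(derived, tree, "X"))

    def test_missing_species_rejected(self, quartet):
        other = parse_newick("((A,B),(C,D));")
        with pytest.raises(TreeError):
            node_displacement(quartet, other, "Z")


class TestSupportedConflict:
    def test_identical_trees_have_none(self):
        t = annotated("((A,B),(C,D));", 0.99)
        flag, _ = supported_conflict(t, t.copy(), "A")
        assert not flag

    def test_forced_quartet_conflict(self):
        ta = annotated("((A,B),(C,D));", 0.99)
        tb = annotated("((A,C),(B,D));", 0.99)
        flag, minsup = supported_conflict(ta, tb, "A")
        assert flag
        assert minsup == pytest.approx(0.99)

    def test_below_threshold_on_one_side_not_supported(self):
        ta = annotated("((A,B),(C,D));", 0.99)
        tb = annotated("((A,C),(B,D));", 0.90)
        flag, _ = supported_conflict(ta, tb, "A", pp_threshold=0.95)
        assert not flag

    def test_one_sided_mode_accepts_single_witness(self):
        ta = annotated("((A,B),(C,D));", 0.99)
        tb = annotated("((A,C),(B,D));", 0.90)
        flag, _ = supported_conflict(ta, tb, "A", pp_threshold=0.95,
                                     both_sides=False)
        assert flag

    def test_missing_annotations_rejected(self):
        ta = parse_newick("((A,B),(C,D));")
        tb = annotated("((A,C),(B,D));")
        with pytest.raises(TreeError, match="support"):
            supported_conflict(ta, tb, "A")


def consensus_pair(scenario):
    cons_cp = majority_rule_consensus(
        bipartition_frequencies([scenario.samples_plastid]))
    cons_nuc = majority_rule_consensus(
        bipartition_frequencies([scenario.samples_nuclear]))
    return cons_cp, cons_nuc


class TestClassification:
    def test_identical_trees_all_congruent(self):
        rng = np.random.default_rng(3)
        tree = random_tree(8, rng)
        pop = TreeSampleSet([tree.copy() for _ in range(10)])
        cons = majority_rule_consensus(bipartition_frequencies([pop]))
        calls = classify_species(cons, cons.copy())
        assert all(c.category == CONGRUENT for c in calls)

    def test_two_event_truth_table_recovered(self):
        cfg = ScenarioConfig(n_taxa=16, displacements=(1, 3), n_samples=10,
                             perturb_rate=0.0, seed=3)
        scenario = generate_scenario(cfg)
        cons_cp, cons_nuc = consensus_pair(scenario)
        calls = classify_species(cons_cp, cons_nuc)
        by_cat = {c.species: c.category for c in calls
                  if c.category != CONGRUENT}
        expected = {s: cat for s, _, cat in scenario.truth_rows()}
        assert by_cat == expected

    def test_category_invariants_hold(self):
        cfg = ScenarioConfig(n_taxa=14, displacements=(2,), n_samples=10,
                             n_capture_events=1, perturb_rate=0.0, seed=5)
        scenario = generate_scenario(cfg)
        calls = classify_species(*consensus_pair(scenario))
        for c in calls:
            c.validate()  # asserts the category/displacement couplings

    def test_report_determinism(self):
        cfg = ScenarioConfig(n_taxa=14, displacements=(1, 2), n_samples=50,
                             perturb_rate=0.03, seed=11)
        scenario = generate_scenario(cfg)
        a = calls_tsv(classify_species(*consensus_pair(scenario)))
        b = calls_tsv(classify_species(*consensus_pair(scenario)))
        assert a == b


class TestAccessionHandling:
    def test_monophyletic_accessions_collapse(self):
        ta = annotated("(((S1a,S1b),(X,Y)),(Z,W));")
        tb = annotated("(((S1a,S1b),(X,Y)),(Z,W));")
        rows = ([("S1a", "S1", g) for g in ("cpDNA", "nrITS")]
                + [("S1b", "S1", g) for g in ("cpDNA", "nrITS")]
                + [(l, l, g) for l in "XYZW" for g in ("cpDNA", "nrITS")])
        tmap = build_taxon_map(rows, ta.leaf_labels(), tb.leaf_labels())
        ca, cb = collapse_accession_pair(ta, tb, tmap)
        assert "S1" in ca.leaf_labels() and "S1a" not in ca.leaf_labels()
        assert ca.leaf_labels() == cb.leaf_labels()

    def test_captured_accession_kept_separate(self):
        # one accession of S1 regrafted in the plastid tree only
        ta = annotated("(((S1a,S1b),(X,Y)),((Z,W),(U,V)));")
        tb = annotated("(((S1a,(Z,W)),(X,Y)),((S1b,(U,V)),Q));")
        tb = annotated("(((S1a,X),(Y,Q)),((S1b,(U,V)),(Z,W)));")
        rows = ([("S1a", "S1", g) for g in ("cpDNA", "nrITS")]
                + [("S1b", "S1", g) for g in ("cpDNA", "nrITS")]
                + [(l, l, g) for l in "XYZWUVQ" for g in ("cpDNA", "nrITS")])
        tmap = build_taxon_map(rows, ta.leaf_labels() | {"Q"},
                               tb.leaf_labels())
        ca, cb = collapse_accession_pair(ta, tb, tmap)
        # S1 is non-monophyletic in tb, so accessions stay apart in both
        assert {"S1a", "S1b"} <= cb.leaf_labels()
        assert {"S1a", "S1b"} <= ca.leaf_labels()


class TestTanglegram:
    def ladder(self, n):
        labels = [f"T{i}" for i in range(n)]
        nwk = labels[0]
        for lab in labels[1:]:
            nwk = f"({nwk},{lab})"
        return annotated(nwk + ";")

    def test_identical_ladders_reach_zero_crossings(self):
        a = self.ladder(8)
        b = self.ladder(8)
        bundle = tanglegram_export(a, b, seed=0)
        assert bundle["crossings"] == 0

    def test_mirrored_ladders_never_get_worse(self):
        a = self.ladder(10)
        b = self.ladder(10)
        for node in b.postorder():
            node.children.reverse()
        from phylodiscord.incongruence import _crossings, _leaf_order

        links = [(s, s) for s in sorted(a.leaf_labels())]
        initial = _crossings(_leaf_order(a), _leaf_order(b), links)
        bundle = tanglegram_export(a, b, seed=0)
        assert bundle["crossings"] <= initial

    def test_links_cover_exactly_shared_species(self):
        rng = np.random.default_rng(9)
        a = random_tree(8, rng)
        b = random_tree(8, rng)
        for t in (a, b):
            for n in t.postorder():
                if not n.is_leaf and n is not t.root:
                    n.support = 1.0
        bundle = tanglegram_export(a, b, seed=1)
        rows = bundle["links_tsv"].strip().splitlines()[1:]
        linked = {r.split("\t")[0] for r in rows}
        assert linked == a.leaf_labels() & b.leaf_labels()

    def test_low_support_edges_flagged(self):
        a = annotated("(((A,B),(C,D)),(E,F));", 0.90)
        b = annotated("(((A,B),(C,D)),(E,F));", 0.99)
        bundle = tanglegram_export(a, b, pp_threshold=0.95, seed=0)
        assert len(bundle["low_support_a"]) == 3
        assert bundle["low_support_b"] == []
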