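"""Bipartition algebra, consensus trees, and internode certainty (IC).

The unit of all computation here is the *bipartition* (split): the two
complementary leaf sets induced by removing an internal edge of an unrooted
tree.  Consensus methods collect splits across a population of trees and
keep those meeting a frequency rule; internode certainty quantifies, for a
consensus branch, how dominant its split is over the most prevalent
conflicting split observed anywhere in the pooled population:

    IC = 1 + p1*log2(p1) + p2*log2(p2)

with p1, p2 the relative frequencies of the branch's split and of its
strongest rival, normalised to sum to 1.  IC = 1 means no conflicting split
was observed at all; IC = 0 means the two occur equally often, as when two
genomes each fully support one of two incompatible resolutions.

Frequencies can be pooled across several tree populations (one per genome)
with explicit weights, defaulting to equal weight per population regardless
of sample counts, so each genome's analysis contributes equally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .treeio import Node, Tree, TreeError, TreeSampleSet

__all__ = [
    "Bipartition",
    "BipartitionFrequencyTable",
    "bipartition_set",
    "bipartition_frequencies",
    "majority_rule_consensus",
    "strict_consensus",
    "semistrict_consensus",
    "internode_certainty",
    "annotate_consensus_with_ic",
    "tree_from_splits",
    "frequency_table_tsv",
]

#: absolute tolerance when comparing pooled frequencies for equality
FREQ_TOL = 1e-12


@dataclass(frozen=True)
class Bipartition:
    """A canonical split of a leaf universe into two complementary sets.

    The stored ``mask`` is the side that excludes the reference leaf (the
    lexicographically smallest label of the universe), making equality and
    hashing well defined: two bipartitions over the same universe are equal
    iff their masks are equal.
    """

    universe: tuple[str, ...]
    mask: frozenset[str]

    @classmethod
    def from_side(cls, universe: Iterable[str], side: Iterable[str]) -> "Bipartition":
        uni = tuple(sorted(universe))
        side = frozenset(side)
        if not side <= set(uni):
            raise ValueError("side is not a subset of the universe")
        if uni[0] in side:
            side = frozenset(uni) - side
        return cls(uni, side)

    @property
    def complement(self) -> frozenset[str]:
        return frozenset(self.universe) - self.mask

    @property
    def smaller_side_size(self) -> int:
        return min(len(self.mask), len(self.universe) - len(self.mask))

    def is_trivial(self) -> bool:
        return self.smaller_side_size < 2

    def compatible_with(self, other: "Bipartition") -> bool:
        """Can both splits occur in one tree (four-intersection rule)?

        Because neither canonical mask contains the reference leaf, the
        complement sides always intersect, and the rule reduces to: masks
        nested or disjoint.
        """
        if self.universe != other.universe:
            raise ValueError("bipartitions are over different universes")
        a, b = self.mask, other.mask
        return a <= b or b <= a or not (a & b)

    def conflicts_with(self, other: "Bipartition") -> bool:
        return not self.compatible_with(other)

    def restrict(self, keep: Iterable[str]) -> "Bipartition":
        """The split induced on a leaf subset (may become trivial)."""
        keep = set(keep)
        return Bipartition.from_side(keep, self.mask & keep)

    def sort_key(self) -> tuple:
        return (len(self.mask), tuple(sorted(self.mask)))

    def __str__(self) -> str:  # dot-star encoding over the sorted universe
        return "".join("*" if lab in self.mask else "." for lab in self.universe)


def bipartition_set(tree: Tree, universe: Sequence[str] | None = None) -> set[Bipartition]:
    """The non-trivial splits of a tree, one per internal unrooted edge.

    ``universe`` defaults to the tree's own leaf set; it may be a superset
    only in the sense of carrying a fixed label order (masks are always
    expressed over the tree's own leaves).
    """
    labels = sorted(tree.leaf_labels())
    if universe is None:
        universe = labels
    else:
        universe = tuple(sorted(universe))
        if set(universe) != set(labels):
            raise TreeError(
                "universe does not match tree leaves; symmetric difference: "
                f"{sorted(set(universe) ^ set(labels))}"
            )
    splits: set[Bipartition] = set()
    if len(labels) < 4:
        return splits
    # postorder accumulation of below-leaf-sets
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.label,))
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node is not tree.root:
            b = Bipartition.from_side(universe, below[id(node)])
            if not b.is_trivial():
                splits.add(b)
    return splits


@dataclass
class BipartitionFrequencyTable:
    """Split frequencies per source population and pooled with weights."""

    universe: tuple[str, ...]
    per_source: list[dict[Bipartition, float]]
    weights: tuple[float, ...]
    source_tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.per_source) != len(self.weights):
            raise ValueError("one weight per source population is required")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"pooling weights must sum to 1, got {sum(self.weights)}")

    @property
    def pooled(self) -> dict[Bipartition, float]:
        out: dict[Bipartition, float] = {}
        for freqs, w in zip(self.per_source, self.weights):
            for b, f in freqs.items():
                out[b] = out.get(b, 0.0) + w * f
        return {b: f for b, f in out.items() if f > FREQ_TOL}

    def frequency(self, b: Bipartition) -> float:
        return sum(w * freqs.get(b, 0.0)
                   for freqs, w in zip(self.per_source, self.weights))

    def splits(self) -> list[Bipartition]:
        return sorted(self.pooled, key=Bipartition.sort_key)


def bipartition_frequencies(
    populations: Sequence[TreeSampleSet],
    weights: Sequence[float] | None = None,
) -> BipartitionFrequencyTable:
    """Count split frequencies per population and pool them.

    All populations must share one leaf universe (prune first if they do
    not).  ``weights`` default to equal weight per population — each
    genome's analysis counts the same even with unequal sample sizes.
    """
    if not populations:
        raise ValueError("at least one tree population is required")
    universe = tuple(sorted(populations[0].leaf_labels()))
    for pop in populations[1:]:
        if tuple(sorted(pop.leaf_labels())) != universe:
            diff = set(universe) ^ pop.leaf_labels()
            raise TreeError(
                f"populations have mismatched leaf sets; symmetric "
                f"difference: {sorted(diff)}"
            )
    if weights is None:
        weights = [1.0 / len(populations)] * len(populations)
    per_source = []
    for pop in populations:
        counts: dict[Bipartition, int] = {}
        for tree in pop:
            for b in bipartition_set(tree, universe):
                counts[b] = counts.get(b, 0) + 1
        n = max(len(pop), 1)
        per_source.append({b: c / n for b, c in counts.items()})
    return BipartitionFrequencyTable(
        universe=universe,
        per_source=per_source,
        weights=tuple(float(w) for w in weights),
        source_tags=tuple(p.genome_tag for p in populations),
    )


# ---------------------------------------------------------------------------
# building a tree from a compatible split set


def tree_from_splits(
    universe: Sequence[str],
    splits: Mapping[Bipartition, tuple[float | None, float | None]] | Iterable[Bipartition],
) -> Tree:
    """Assemble the unique unrooted tree containing a compatible split set.

    ``splits`` maps each bipartition to an optional ``(support, ic)`` pair.
    The construction roots the tree at the reference leaf: every canonical
    mask is then a clade, and clades nest by containment.
    """
    if not isinstance(splits, Mapping):
        splits = {b: (None, None) for b in splits}
    universe = tuple(sorted(universe))
    ref = universe[0]
    clades = sorted(splits, key=lambda b: (-len(b.mask), tuple(sorted(b.mask))))
    for i, a in enumerate(clades):
        for b in clades[i + 1:]:
            if a.conflicts_with(b):
                raise TreeError(f"splits are not pairwise compatible: {a} vs {b}")

    root = Node()
    root.add_child(Node(label=ref))
    node_of: list[tuple[frozenset[str], Node]] = []  # insertion order = size desc
    for b in clades:
        parent = root
        for mask, nd in node_of:
            if b.mask < mask:
                parent = nd  # smallest strict superset seen so far (sorted desc)
        new = Node()
        support, ic = splits[b]
        new.support = support
        new.ic = ic
        # re-parent any already-placed clades that nest inside b
        for mask, nd in node_of:
            if mask < b.mask and nd.parent is parent:
                parent.remove_child(nd)
                new.add_child(nd)
        parent.add_child(new)
        node_of.append((b.mask, new))
    for lab in universe[1:]:
        parent = root
        best: frozenset[str] | None = None
        for mask, nd in node_of:
            if lab in mask and (best is None or mask < best):
                parent, best = nd, mask
        parent.add_child(Node(label=lab))
    tree = Tree(root, rooted=False)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# consensus methods


def majority_rule_consensus(
    table: BipartitionFrequencyTable,
    threshold: float = 0.5,
    strict_greater: bool = True,
) -> Tree:
    """Majority-rule consensus from pooled split frequencies.

    Includes every non-trivial split with pooled frequency strictly above
    ``threshold`` (such splits are automatically pairwise compatible), and,
    when ``threshold`` is 0.5, greedily completes with splits at exactly
    0.5 in descending frequency, ties broken lexicographically on the
    canonical mask, keeping only splits compatible with those accepted.
    Edges are annotated with their pooled frequency as support.
    """
    if not 0.5 <= threshold <= 1.0:
        raise ValueError(f"consensus threshold must be in [0.5, 1], got {threshold}")
    pooled = table.pooled
    accepted: dict[Bipartition, tuple[float | None, float | None]] = {}
    order = sorted(pooled.items(),
                   key=lambda kv: (-kv[1], kv[0].sort_key()))
    for b, f in order:
        if b.is_trivial():
            continue
        include = f > threshold + FREQ_TOL if strict_greater else f >= threshold - FREQ_TOL
        at_tie = (abs(threshold - 0.5) <= FREQ_TOL
                  and abs(f - 0.5) <= FREQ_TOL)
        if include or at_tie:
            if all(b.compatible_with(other) for other in accepted):
                accepted[b] = (f, None)
    return tree_from_splits(table.universe, accepted)


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """The tree containing exactly the splits present in every input."""
    if not trees:
        raise ValueError("at least one tree is required")
    universe = tuple(sorted(trees[0].leaf_labels()))
    common = bipartition_set(trees[0], universe)
    for t in trees[1:]:
        common &= bipartition_set(t, universe)
    return tree_from_splits(universe, {b: (1.0, None) for b in common})


def semistrict_consensus(trees: Sequence[Tree]) -> Tree:
    """Combinable-component consensus.

    Keeps every split appearing in at least one input and conflicting with
    no split of any input.  Retained splits are pairwise compatible because
    each is itself an observed split.
    """
    if not trees:
        raise ValueError("at least one tree is required")
    universe = tuple(sorted(trees[0].leaf_labels()))
    per_tree = [bipartition_set(t, universe) for t in trees]
    union = set().union(*per_tree)
    kept = {
        b for b in union
        if all(b.compatible_with(other) for splits in per_tree for other in splits)
    }
    return tree_from_splits(universe, {b: (None, None) for b in kept})


# ---------------------------------------------------------------------------
# internode certainty


def _entropy_certainty(p1: float) -> float:
    p2 = 1.0 - p1
    acc = 1.0
    for p in (p1, p2):
        if p > 0.0:
            acc += p * math.log2(p)
    return min(1.0, max(0.0, acc))


def max_conflicting_frequency(
    table: BipartitionFrequencyTable, b: Bipartition
) -> tuple[Bipartition | None, float]:
    """The most prevalent split incompatible with ``b`` in the pooled table."""
    best: Bipartition | None = None
    best_f = 0.0
    for other, f in table.pooled.items():
        if other == b or other.is_trivial():
            continue
        if b.conflicts_with(other) and (f > best_f + FREQ_TOL
                                        or (abs(f - best_f) <= FREQ_TOL and best is not None
                                            and other.sort_key() < best.sort_key())):
            best, best_f = other, f
    return best, best_f


def internode_certainty(table: BipartitionFrequencyTable, b: Bipartition) -> float:
    """Internode certainty of split ``b`` against its strongest rival.

    Only the single most prevalent conflicting split enters the two-term
    entropy; with no observed conflict IC is 1 by convention.
    """
    f_b = table.frequency(b)
    if f_b <= 0.0:
        raise ValueError("internode certainty is undefined for an unobserved split")
    _, f_c = max_conflicting_frequency(table, b)
    if f_c <= FREQ_TOL:
        return 1.0
    p1 = f_b / (f_b + f_c)
    return _entropy_certainty(p1)


def annotate_consensus_with_ic(consensus: Tree,
                               table: BipartitionFrequencyTable) -> Tree:
    """Attach IC values to every internal edge of a consensus tree.

    Every consensus split must be present in the table; leaf edges are left
    unannotated.
    """
    out = consensus.copy()
    universe = tuple(sorted(out.leaf_labels()))
    if universe != table.universe:
        raise TreeError("consensus tree and frequency table have different universes")
    below: dict[int, frozenset[str]] = {}
    pooled = table.pooled
    for node in out.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.label,))
            continue
        below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node is out.root:
            continue
        b = Bipartition.from_side(universe, below[id(node)])
        if b.is_trivial():
            continue
        if b not in pooled:
            raise TreeError(f"consensus split {b} missing from frequency table")
        node.ic = internode_certainty(table, b)
    return out


# ---------------------------------------------------------------------------
# export


def frequency_table_tsv(table: BipartitionFrequencyTable) -> str:
    """Frequency table as TSV: split, per-source freqs, pooled, top conflict, IC."""
    tags = table.source_tags or tuple(
        f"source{i + 1}" for i in range(len(table.per_source)))
    lines = ["\t".join(["split"] + [f"freq_{t}" for t in tags]
                       + ["pooled_freq", "top_conflict_freq", "ic"])]
    for b in table.splits():
        if b.is_trivial():
            continue
        per = [f"{freqs.get(b, 0.0):.6f}" for freqs in table.per_source]
        _, f_c = max_conflicting_frequency(table, b)
        ic = internode_certainty(table, b)
        lines.append("\t".join([str(b)] + per +
                               [f"{table.frequency(b):.6f}", f"{f_c:.6f}", f"{ic:.4f}"]))
    return "\n".join(lines) + "\n"
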