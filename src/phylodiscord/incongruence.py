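"""Per-species conflict detection between two genome consensus trees.

Given the nuclear and chloroplast consensus trees (edges annotated with
posterior support), this module decides for each shared species whether its
two placements are in *supported* conflict (both witnessing clades above a
posterior-probability threshold, 0.95 by default), measures how far apart
the placements are in nodes, and sorts species into the two classical
explanations of cytonuclear discordance:

* displacement of one node — compatible with incomplete lineage sorting
  (ILS candidate);
* displacement of two or more nodes — more plausibly genomic exchange via
  hybridisation, i.e. chloroplast capture (hybridisation candidate).

"Position" is operationalised through sibling-context matching: the node
displacement of a species is the edge-adjacency (line-graph) distance, in
the tree with the species removed, between its actual attachment edge and
the edge whose subtended leaf set best matches the species' sibling clade
in the other tree (maximum Jaccard overlap; ties resolved to the nearest
edge).  The metric is symmetrised by taking the maximum over the two
directions.  A single nearest-neighbour regraft scores 1 and a k-step
regraft scores k.

Because one captured species perturbs splits shared with its neighbours,
per-species attribution uses an iterative scheme: the species whose removal
resolves the most supported conflicting split pairs is flagged, pruned from
both trees, and the search repeats until no supported conflict remains.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .consensus import Bipartition, bipartition_set
from .treeio import Node, Tree, TreeError, write_newick

__all__ = [
    "TaxonMap",
    "IncongruenceCall",
    "build_taxon_map",
    "prune_to_shared",
    "attachment_context",
    "node_displacement",
    "supported_conflict",
    "classify_species",
    "collapse_accession_pair",
    "summarise_calls",
    "calls_tsv",
    "tanglegram_export",
]

CONGRUENT = "congruent"
ILS_CANDIDATE = "ILS-candidate"
HYBRIDISATION_CANDIDATE = "hybridisation-candidate"


# ---------------------------------------------------------------------------
# taxon map


@dataclass
class TaxonMap:
    """Accession-to-species mapping for two genome analyses."""

    accession_to_species: dict[str, str]
    species_accessions: dict[str, dict[str, list[str]]]  # species -> genome -> accessions
    shared_species: set[str]
    unmapped: dict[str, list[str]] = field(default_factory=dict)

    def accessions(self, species: str, genome: str) -> list[str]:
        return self.species_accessions.get(species, {}).get(genome, [])


def build_taxon_map(
    rows: list[tuple[str, str, str]],
    labels_a: set[str],
    labels_b: set[str],
    genome_a: str = "cpDNA",
    genome_b: str = "nrITS",
) -> TaxonMap:
    """Build a :class:`TaxonMap` from (accession, species, genome) rows.

    An accession mapped to two different species is an error; exact
    duplicate rows are tolerated and deduplicated.  Labels present in a
    sample set but absent from the mapping are reported in ``unmapped``.
    """
    acc_to_sp: dict[str, str] = {}
    sp_acc: dict[str, dict[str, list[str]]] = {}
    seen: set[tuple[str, str, str]] = set()
    for accession, species, genome in rows:
        accession, species, genome = (accession.strip(), species.strip(), genome.strip())
        row = (accession, species, genome)
        if row in seen:
            continue
        seen.add(row)
        key = (accession, genome)
        prior = acc_to_sp.get(f"{genome}:{accession}")
        if prior is not None and prior != species:
            raise ValueError(
                f"accession {accession!r} ({genome}) mapped to two species: "
                f"{prior!r} and {species!r}"
            )
        acc_to_sp[f"{genome}:{accession}"] = species
        sp_acc.setdefault(species, {}).setdefault(genome, []).append(accession)
    species_a = {sp for sp, g in sp_acc.items()
                 if any(acc in labels_a for acc in g.get(genome_a, []))}
    species_b = {sp for sp, g in sp_acc.items()
                 if any(acc in labels_b for acc in g.get(genome_b, []))}
    mapped_a = {acc for sp, g in sp_acc.items() for acc in g.get(genome_a, [])}
    mapped_b = {acc for sp, g in sp_acc.items() for acc in g.get(genome_b, [])}
    unmapped = {
        genome_a: sorted(labels_a - mapped_a),
        genome_b: sorted(labels_b - mapped_b),
    }
    return TaxonMap(
        accession_to_species={k.split(":", 1)[1]: v for k, v in acc_to_sp.items()},
        species_accessions=sp_acc,
        shared_species=species_a & species_b,
        unmapped=unmapped,
    )


def prune_to_shared(tree: Tree, keep: set[str]) -> Tree:
    """Induced subtree on ``keep`` (|keep| >= 3), annotations preserved."""
    return tree.prune_to(keep)


# ---------------------------------------------------------------------------
# attachment context and displacement


@dataclass
class AttachmentContext:
    """Where a leaf sits: its sibling leaf set and the nested shells beyond.

    ``shells[0]`` is the sibling set (leaves sharing the attachment node);
    ``shells[k]`` holds the new leaves met at the k-th node walking from
    the leaf toward the root.
    """

    leaf: str
    shells: list[frozenset[str]]

    @property
    def sibling_set(self) -> frozenset[str]:
        return self.shells[0]


def attachment_context(tree: Tree, leaf: str) -> AttachmentContext:
    """Nested leaf-set shells around a leaf's attachment point."""
    work = tree
    node = work.find_leaf(leaf)
    shells: list[frozenset[str]] = []
    seen = {leaf}
    current = node.parent
    prev = node
    while current is not None:
        members = set()
        for child in current.children:
            if child is prev:
                continue
            members.update(l.label for l in Tree(child).leaves())
        shell = frozenset(members - seen)
        if shell:
            shells.append(shell)
            seen |= shell
        prev, current = current, current.parent
    return AttachmentContext(leaf=leaf, shells=shells)


class _EdgeGraph:
    """Unrooted-edge view of a rooted tree for line-graph distances."""

    def __init__(self, tree: Tree):
        work = tree.copy()
        work.suppress_root_degree2()
        self.tree = work
        self.universe = frozenset(work.leaf_labels())
        # every non-root node <-> the edge to its parent; with a root of
        # degree >= 3 these are exactly the unrooted edges
        self.edges: list[Node] = [n for n in work.postorder() if n is not work.root]
        self.index = {id(n): i for i, n in enumerate(self.edges)}
        self.below: dict[int, frozenset[str]] = {}
        for n in work.postorder():
            if n.is_leaf:
                self.below[id(n)] = frozenset((n.label,))
            else:
                self.below[id(n)] = frozenset().union(
                    *(self.below[id(c)] for c in n.children))
        # line-graph adjacency: edges share a node iff same parent,
        # or one's child node is the other's parent
        self.adjacent: list[list[int]] = [[] for _ in self.edges]
        for i, n in enumerate(self.edges):
            for c in n.children:
                j = self.index[id(c)]
                self.adjacent[i].append(j)
                self.adjacent[j].append(i)
            p = n.parent
            if p is not None:
                for sib in p.children:
                    if sib is not n and id(sib) in self.index:
                        self.adjacent[i].append(self.index[id(sib)])

    def side_sets(self, i: int) -> tuple[frozenset[str], frozenset[str]]:
        b = self.below[id(self.edges[i])]
        return b, self.universe - b

    def distances_from(self, sources: set[int]) -> list[int]:
        dist = [-1] * len(self.edges)
        dq: deque[int] = deque()
        for s in sources:
            dist[s] = 0
            dq.append(s)
        while dq:
            u = dq.popleft()
            for v in self.adjacent[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    dq.append(v)
        return dist


def _remove_leaf_get_attachment(tree: Tree, leaf: str) -> tuple[Tree, set[frozenset[str]]]:
    """Remove a leaf; return the reduced tree and its former attachment.

    The attachment is reported as a set of below-leaf-sets identifying
    candidate edges of the reduced tree (several when the leaf sat in a
    polytomy or at the root).
    """
    work = tree.copy()
    work.suppress_root_degree2()
    node = work.find_leaf(leaf)
    parent = node.parent
    if parent is None:
        raise TreeError("cannot remove the root leaf")
    parent.remove_child(node)
    anchors: set[frozenset[str]] = set()
    if len(parent.children) == 1:
        child = parent.children[0]
        anchors.add(frozenset(l.label for l in Tree(child).leaves()))
    else:
        for child in parent.children:
            anchors.add(frozenset(l.label for l in Tree(child).leaves()))
    work.suppress_unary()
    work.suppress_root_degree2()
    return work, anchors


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def _unrooted_sibling_context(tree: Tree, leaf: str) -> frozenset[str]:
    """Rooting-invariant sibling context of a leaf.

    The leaf's attachment node carries several neighbour subtrees; the
    largest is taken to be the "rest of the tree" direction and the
    context is the union of the others — the clade(s) the leaf sits
    among, regardless of where the tree happens to be rooted.
    """
    work = tree.copy()
    work.suppress_root_degree2()
    node = work.find_leaf(leaf)
    parent = node.parent
    universe = work.leaf_labels()
    neighbour_sets: list[frozenset[str]] = []
    for child in parent.children:
        if child is node:
            continue
        neighbour_sets.append(frozenset(l.label for l in Tree(child).leaves()))
    if parent is not work.root:
        below_parent = {l.label for l in Tree(parent).leaves()}
        neighbour_sets.append(frozenset(universe - below_parent))
    largest = max(neighbour_sets, key=lambda s: (len(s), tuple(sorted(s))))
    rest = [s for s in neighbour_sets if s is not largest]
    if not rest:
        return largest
    return frozenset().union(*rest)


def _directional_displacement(src: Tree, dst: Tree, species: str) -> int:
    """Displacement of ``species`` judged by its context in ``src``,
    measured on ``dst`` minus the species."""
    ctx = _unrooted_sibling_context(src, species)
    reduced, anchors = _remove_leaf_get_attachment(dst, species)
    graph = _EdgeGraph(reduced)
    actual = {
        i for i in range(len(graph.edges))
        if graph.below[id(graph.edges[i])] in anchors
    }
    if not actual:
        # anchors may correspond to complements after re-rooting
        actual = {
            i for i in range(len(graph.edges))
            if (graph.universe - graph.below[id(graph.edges[i])]) in anchors
        }
    if not actual:
        raise TreeError(f"could not locate the attachment edge of {species!r}")
    scores = []
    for i in range(len(graph.edges)):
        lo, hi = graph.side_sets(i)
        scores.append(max(_jaccard(ctx, lo), _jaccard(ctx, hi)))
    best_score = max(scores)
    candidates = {i for i, s in enumerate(scores) if s >= best_score - 1e-12}
    dist = graph.distances_from(actual)
    return min(dist[i] for i in candidates)


def node_displacement(cons_a: Tree, cons_b: Tree, species: str) -> int:
    """Topological displacement of one species between two trees.

    Zero iff the species' sibling contexts match exactly; 1 for a single
    nearest-neighbour regraft; grows with regraft distance.  Symmetric by
    construction (maximum over both directions).
    """
    for tree in (cons_a, cons_b):
        if species not in tree.leaf_labels():
            raise TreeError(f"species {species!r} missing from a consensus tree")
    if cons_a.leaf_labels() != cons_b.leaf_labels():
        raise TreeError("consensus trees must be pruned to a shared leaf set first")
    d_ab = _directional_displacement(cons_a, cons_b, species)
    d_ba = _directional_displacement(cons_b, cons_a, species)
    return max(d_ab, d_ba)


# ---------------------------------------------------------------------------
# supported conflict


def _supported_splits(tree: Tree, threshold: float) -> dict[Bipartition, float]:
    universe = tuple(sorted(tree.leaf_labels()))
    out: dict[Bipartition, float] = {}
    below: dict[int, frozenset[str]] = {}
    missing_support = False
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.label,))
            continue
        below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node is tree.root:
            continue
        b = Bipartition.from_side(universe, below[id(node)])
        if b.is_trivial():
            continue
        if node.support is None:
            missing_support = True
            continue
        if node.support > threshold:
            out[b] = max(out.get(b, 0.0), node.support)
    if missing_support and not out:
        raise TreeError("consensus tree carries no support annotations")
    return out


def _all_annotated_splits(tree: Tree) -> dict[Bipartition, float]:
    universe = tuple(sorted(tree.leaf_labels()))
    out: dict[Bipartition, float] = {}
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.label,))
            continue
        below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node is tree.root:
            continue
        b = Bipartition.from_side(universe, below[id(node)])
        if b.is_trivial():
            continue
        if node.support is None:
            raise TreeError("consensus tree edge lacks a support annotation")
        out[b] = max(out.get(b, 0.0), node.support)
    return out


def _conflicting_pairs(
    splits_a: dict[Bipartition, float],
    splits_b: dict[Bipartition, float],
    threshold: float,
    both_sides: bool,
) -> list[tuple[Bipartition, Bipartition, float]]:
    pairs = []
    for sa, fa in splits_a.items():
        for sb, fb in splits_b.items():
            if not sa.conflicts_with(sb):
                continue
            if both_sides:
                ok = fa > threshold and fb > threshold
            else:
                ok = fa > threshold or fb > threshold
            if ok:
                pairs.append((sa, sb, min(fa, fb)))
    return pairs


def _pair_resolved_by(sa: Bipartition, sb: Bipartition, species: str) -> bool:
    keep = set(sa.universe) - {species}
    if len(keep) < 4:
        return True
    return not sa.restrict(keep).conflicts_with(sb.restrict(keep))


def supported_conflict(
    cons_a: Tree,
    cons_b: Tree,
    species: str,
    pp_threshold: float = 0.95,
    both_sides: bool = True,
) -> tuple[bool, float | None]:
    """Is the species' position in supported conflict between the trees?

    True iff some split of tree A and some split of tree B, each above the
    posterior threshold (both sides by default; one side if ``both_sides``
    is False), are incompatible *and* become compatible once the species is
    removed — i.e. the species' placement is what the pair disagrees about.
    Returns the flag and the min support of the strongest witnessing pair.
    """
    splits_a = _all_annotated_splits(cons_a)
    splits_b = _all_annotated_splits(cons_b)
    best: float | None = None
    for sa, sb, minsup in _conflicting_pairs(splits_a, splits_b,
                                             pp_threshold, both_sides):
        if _pair_resolved_by(sa, sb, species):
            best = minsup if best is None else max(best, minsup)
    return best is not None, best


# ---------------------------------------------------------------------------
# classification


@dataclass
class IncongruenceCall:
    """Per-species record of the conflict assessment."""

    species: str
    supported_conflict: bool
    displacement: int | None
    min_support: float | None
    category: str

    def validate(self) -> None:
        if self.category == CONGRUENT:
            assert not self.supported_conflict
        elif self.category == ILS_CANDIDATE:
            assert self.supported_conflict and self.displacement == 1
        elif self.category == HYBRIDISATION_CANDIDATE:
            assert self.supported_conflict and self.displacement >= 2
        else:  # pragma: no cover
            raise AssertionError(f"unknown category {self.category!r}")


def _is_monophyletic(tree: Tree, labels: set[str]) -> bool:
    """Unrooted monophyly: an edge separates ``labels`` from the rest."""
    universe = tree.leaf_labels()
    if len(labels) <= 1 or len(universe - labels) <= 1:
        return True
    split = Bipartition.from_side(sorted(universe), labels)
    return split in bipartition_set(tree)


def _collapse_clade(work: Tree, accset: set[str], species: str) -> Tree:
    """Replace the clade of ``accset`` by a single leaf named ``species``.

    The accessions may straddle the stored root (monophyly is unrooted);
    the tree is then re-rooted at a leaf outside the set first.
    """
    clade_node = _mrca(work, accset)
    if {l.label for l in Tree(clade_node).leaves()} != accset:
        outside = min(work.leaf_labels() - accset)
        work = work.reroot_at_leaf(outside)
        clade_node = _mrca(work, accset)
    if clade_node.is_leaf:
        clade_node.label = species
        return work
    parent = clade_node.parent
    if parent is None:
        raise TreeError(f"accessions of {species!r} span the whole tree")
    leaf = Node(label=species, length=clade_node.length,
                support=clade_node.support)
    idx = parent.children.index(clade_node)
    parent.children[idx] = leaf
    leaf.parent = parent
    return work


def collapse_accession_pair(
    tree_a: Tree, tree_b: Tree, taxon_map: TaxonMap,
    genome_a: str = "cpDNA", genome_b: str = "nrITS",
) -> tuple[Tree, Tree]:
    """Species-level views of two accession-labelled consensus trees.

    A species' accessions are collapsed to one leaf named after the species
    only when they are monophyletic (within each genome) in *both* trees;
    otherwise all its accession terminals keep their own labels and are
    classified separately — the pattern of a single captured accession
    sitting apart from its congruent conspecifics.
    """
    wa, wb = tree_a.copy(), tree_b.copy()
    labels_a, labels_b = wa.leaf_labels(), wb.leaf_labels()
    for species, genomes in sorted(taxon_map.species_accessions.items()):
        accs_a = {a for a in genomes.get(genome_a, []) if a in labels_a}
        accs_b = {a for a in genomes.get(genome_b, []) if a in labels_b}
        if not accs_a or not accs_b:
            continue
        mono_a = len(accs_a) == 1 or _is_monophyletic(wa, accs_a)
        mono_b = len(accs_b) == 1 or _is_monophyletic(wb, accs_b)
        if mono_a and mono_b:
            wa = _collapse_clade(wa, accs_a, species)
            wb = _collapse_clade(wb, accs_b, species)
        # else: accession terminals keep their labels in both trees
    return wa, wb


def _mrca(tree: Tree, labels: set[str]) -> Node:
    below: dict[int, set[str]] = {}
    best: Node | None = None
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = {node.label}
        else:
            below[id(node)] = set().union(*(below[id(c)] for c in node.children))
        if labels <= below[id(node)]:
            if best is None:
                best = node
    if best is None:
        raise TreeError(f"labels {sorted(labels)} not all present")
    return best


def classify_species(
    cons_a: Tree,
    cons_b: Tree,
    taxon_map: TaxonMap | None = None,
    pp_threshold: float = 0.95,
    both_sides: bool = True,
    genome_a: str = "cpDNA",
    genome_b: str = "nrITS",
) -> list[IncongruenceCall]:
    """Classify every shared species as congruent, ILS- or hybridisation-candidate.

    Conflicts are attributed iteratively: among all supported conflicting
    split pairs, the species resolving the most pairs when removed is
    flagged, pruned from both trees and the search repeats.  Flagged
    species then get their node displacement measured on the trees pruned
    of the *other* flagged species, so each event is scored on an otherwise
    agreeing background.

    When a taxon map is given the input trees are accession-labelled:
    monophyletic accession sets are collapsed to one species leaf and
    non-monophyletic accessions are classified separately.
    """
    if taxon_map is not None:
        cons_a, cons_b = collapse_accession_pair(
            cons_a, cons_b, taxon_map, genome_a=genome_a, genome_b=genome_b)
    ta, tb = cons_a.copy(), cons_b.copy()
    shared = sorted(ta.leaf_labels() & tb.leaf_labels())
    if len(shared) < 4:
        raise TreeError("classification needs at least 4 shared species")
    ta = ta.prune_to(shared)
    tb = tb.prune_to(shared)

    flagged: list[str] = []
    witness_support: dict[str, float] = {}
    cur_a, cur_b = ta, tb
    while len(cur_a.leaf_labels()) >= 4:
        splits_a = _all_annotated_splits(cur_a)
        splits_b = _all_annotated_splits(cur_b)
        pairs = _conflicting_pairs(splits_a, splits_b, pp_threshold, both_sides)
        if not pairs:
            break
        present = sorted(cur_a.leaf_labels())
        resolved_counts: dict[str, int] = {}
        support_best: dict[str, float] = {}
        for sp in present:
            count = 0
            best = 0.0
            for sa, sb, minsup in pairs:
                if _pair_resolved_by(sa, sb, sp):
                    count += 1
                    best = max(best, minsup)
            if count:
                resolved_counts[sp] = count
                support_best[sp] = best
        if not resolved_counts:
            break  # conflict not attributable to any single species
        top = max(resolved_counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
        flagged.append(top)
        witness_support[top] = support_best[top]
        remaining = set(cur_a.leaf_labels()) - {top}
        if len(remaining) < 4:
            break
        cur_a = cur_a.prune_to(remaining)
        cur_b = cur_b.prune_to(remaining)

    calls = []
    for sp in shared:
        if sp not in flagged:
            calls.append(IncongruenceCall(sp, False, None, None, CONGRUENT))
            continue
        keep = set(shared) - (set(flagged) - {sp})
        if len(keep) >= 4:
            d = node_displacement(ta.prune_to(keep), tb.prune_to(keep), sp)
        else:
            d = node_displacement(ta, tb, sp)
        d = max(d, 1)  # a flagged species is displaced by definition
        category = ILS_CANDIDATE if d == 1 else HYBRIDISATION_CANDIDATE
        calls.append(IncongruenceCall(sp, True, d, witness_support[sp], category))
    for c in calls:
        c.validate()
    return calls


def summarise_calls(calls: list[IncongruenceCall]) -> dict:
    counts = {CONGRUENT: 0, ILS_CANDIDATE: 0, HYBRIDISATION_CANDIDATE: 0}
    for c in calls:
        counts[c.category] += 1
    return {
        "n_species": len(calls),
        "category_counts": counts,
        "ils_candidates": sorted(c.species for c in calls
                                 if c.category == ILS_CANDIDATE),
        "hybridisation_candidates": sorted(c.species for c in calls
                                           if c.category == HYBRIDISATION_CANDIDATE),
    }


def calls_tsv(calls: list[IncongruenceCall]) -> str:
    lines = ["species\tsupported_conflict\tmin_support\tdisplacement\tcategory"]
    for c in sorted(calls, key=lambda c: c.species):
        lines.append("\t".join([
            c.species,
            "1" if c.supported_conflict else "0",
            "" if c.min_support is None else f"{c.min_support:.4f}",
            "" if c.displacement is None else str(c.displacement),
            c.category,
        ]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# tanglegram


_CATEGORY_COLOURS = {
    CONGRUENT: "#4d4d4d",
    ILS_CANDIDATE: "#1f77b4",
    HYBRIDISATION_CANDIDATE: "#d62728",
}


def _leaf_order(tree: Tree) -> list[str]:
    return [n.label for n in tree.postorder() if n.is_leaf]


def _crossings(order_a: list[str], order_b: list[str],
               links: list[tuple[str, str]]) -> int:
    pos_a = {lab: i for i, lab in enumerate(order_a)}
    pos_b = {lab: i for i, lab in enumerate(order_b)}
    pts = [(pos_a[a], pos_b[b]) for a, b in links
           if a in pos_a and b in pos_b]
    n = 0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if (pts[i][0] - pts[j][0]) * (pts[i][1] - pts[j][1]) < 0:
                n += 1
    return n


def tanglegram_export(
    cons_a: Tree,
    cons_b: Tree,
    links: list[tuple[str, str]] | None = None,
    calls: list[IncongruenceCall] | None = None,
    pp_threshold: float = 0.95,
    seed: int = 0,
    iterations: int = 2000,
) -> dict:
    """Two trees with leaf orders optimised to reduce tanglegram crossings.

    Hill climbing over random child-order flips with a fixed iteration
    budget and seed; monotone in the crossing count.  Returns newick
    strings, the achieved crossing count, per-species link rows (TSV), per
    -category colours, and the low-support edges (support < threshold) of
    each tree.
    """
    a, b = cons_a.copy(), cons_b.copy()
    if links is None:
        shared = sorted(a.leaf_labels() & b.leaf_labels())
        links = [(s, s) for s in shared]
    rng = np.random.default_rng(seed)
    best = _crossings(_leaf_order(a), _leaf_order(b), links)
    internals = ([(0, n) for n in a.postorder() if not n.is_leaf]
                 + [(1, n) for n in b.postorder() if not n.is_leaf])
    for _ in range(iterations):
        if best == 0 or not internals:
            break
        _, node = internals[rng.integers(len(internals))]
        node.children.reverse()
        now = _crossings(_leaf_order(a), _leaf_order(b), links)
        if now <= best:
            best = now
        else:
            node.children.reverse()

    def low_support(tree: Tree) -> list[str]:
        out = set()
        universe = tuple(sorted(tree.leaf_labels()))
        below: dict[int, frozenset[str]] = {}
        for node in tree.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset((node.label,))
                continue
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node is tree.root or node.support is None:
                continue
            bp = Bipartition.from_side(universe, below[id(node)])
            if not bp.is_trivial() and node.support < pp_threshold:
                out.add(str(bp))
        return sorted(out)

    categories = {c.species: c.category for c in calls} if calls else {}
    link_lines = ["left\tright\tcategory\tcolour"]
    for la, lb in links:
        cat = categories.get(la, categories.get(lb, CONGRUENT))
        link_lines.append(f"{la}\t{lb}\t{cat}\t{_CATEGORY_COLOURS[cat]}")
    return {
        "newick_a": write_newick(a, include_support=True, include_lengths=False),
        "newick_b": write_newick(b, include_support=True, include_lengths=False),
        "crossings": best,
        "links_tsv": "\n".join(link_lines) + "\n",
        "colours": dict(_CATEGORY_COLOURS),
        "low_support_a": low_support(a),
        "low_support_b": low_support(b),
        "seed": seed,
    }
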