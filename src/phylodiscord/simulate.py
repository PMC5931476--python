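"""Synthetic test worlds with known, implanted chloroplast-capture events.

A scenario consists of a base ("species"/nuclear) topology, a derived
("chloroplast") topology obtained by regrafting selected species, two
posterior-like tree populations, a pair of alignments, a taxon map and a
truth table.  Every downstream stage of the pipeline can therefore be
tested against known ground truth without any external data.

Design notes:

* The posterior emulator perturbs each internal edge of the generating
  topology independently: with probability ``perturb_rate`` the sample
  receives a random nearest-neighbour interchange at that edge, drawn
  uniformly from the three resolutions (one of which is the original).
  The expected support of a true split is therefore
  ``1 - perturb_rate * 2/3`` — analytically predictable, which is the
  point of emulating rather than running real MCMC.
* Capture is modelled as a topological regraft of one leaf (or one
  accession of a multi-accession species); the statistics downstream are
  topology-only, so no branch-length model of introgression timing is
  attempted.
* Implanted events are constrained so that the ground truth is
  identifiable from topology alone: a moved species must have a sibling
  clade of at least two leaves, the destination edge must subtend at least
  two leaves, and events may not share context leaves.  Without these
  constraints a one-step move is topologically symmetric between several
  species and no truth table could be reproduced exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .incongruence import node_displacement
from .treeio import (Node, Tree, TreeError, TreeSampleSet, write_newick,
                     write_nexus_trees)

__all__ = [
    "CaptureEvent",
    "CaptureScenario",
    "ScenarioConfig",
    "simulate_species_tree",
    "inject_capture",
    "emulate_posterior",
    "simulate_alignment",
    "generate_scenario",
    "write_scenario",
]


def _rng_of(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(n_taxa: int, seed=0) -> Tree:
    """A Yule (pure-birth) tree with ``n_taxa`` leaves.

    At each step a uniformly chosen extant lineage splits after a
    unit-exponential waiting time; leaves are finally extended to the
    present by one more unit-exponential draw and labelled ``sp01``,
    ``sp02``, ... in traversal order.
    """
    if n_taxa < 4:
        raise ValueError("a usable species tree needs at least 4 taxa")
    rng = _rng_of(seed)
    root = Node(length=None)
    tips: list[Node] = []
    for _ in range(2):
        child = Node(length=0.0)
        root.add_child(child)
        tips.append(child)
    while len(tips) < n_taxa:
        wait = rng.exponential(1.0)
        for tip in tips:
            tip.length += wait
        victim = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            child = Node(length=0.0)
            victim.add_child(child)
            tips.append(child)
    final = rng.exponential(1.0)
    for tip in tips:
        tip.length += final
    tree = Tree(root, rooted=True)
    # random label assignment keeps the labelled-topology distribution
    # exchangeable (labelling in traversal order would canonicalise it)
    leaves = tree.leaves()
    labels = [f"sp{i + 1:02d}" for i in range(n_taxa)]
    for leaf, j in zip(leaves, rng.permutation(n_taxa)):
        leaf.label = labels[j]
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# capture injection


@dataclass
class CaptureEvent:
    """One implanted regraft: which species moved, from where to where."""

    species: str
    source_siblings: tuple[str, ...]
    destination_clade: tuple[str, ...]
    displacement: int


def _regraft_leaf(tree: Tree, species: str, dest_clade: frozenset[str]) -> Tree:
    """Move a leaf onto the edge above the clade with the given leaf set."""
    out = tree.copy()
    out.suppress_root_degree2()
    leaf = out.find_leaf(species)
    parent = leaf.parent
    parent.remove_child(leaf)
    out.suppress_unary()
    out.suppress_root_degree2()
    target = None
    for node in out.postorder():
        if node is out.root:
            continue
        leaves = frozenset(l.label for l in Tree(node).leaves())
        if leaves == dest_clade:
            target = node
            break
    if target is None:
        raise TreeError(f"destination clade {sorted(dest_clade)} not found")
    tparent = target.parent
    mid = Node(length=(target.length or 0.0) / 2)
    idx = tparent.children.index(target)
    tparent.children[idx] = mid
    mid.parent = tparent
    if target.length is not None:
        target.length /= 2
    mid.add_child(target)
    leaf.parent = None
    mid.add_child(leaf)
    return out


def _candidate_destinations(tree: Tree, species: str) -> list[frozenset[str]]:
    work = tree.copy()
    work.suppress_root_degree2()
    leaf = work.find_leaf(species)
    leaf.parent.remove_child(leaf)
    work.suppress_unary()
    work.suppress_root_degree2()
    out = []
    for node in work.postorder():
        if node is work.root:
            continue
        out.append(frozenset(l.label for l in Tree(node).leaves()))
    return out


def inject_capture(tree: Tree, species: str, target_displacement: int,
                   seed=0) -> tuple[Tree, CaptureEvent]:
    """Regraft ``species`` so its measured node displacement equals the target.

    Candidate destination edges are enumerated, the regraft performed, and
    the displacement measured with the same metric the classifier uses; a
    candidate achieving the target is chosen at random (seeded).  If the
    target is unreachable the error reports the achievable maximum.
    """
    if target_displacement < 1:
        raise ValueError("target displacement must be >= 1")
    if species not in tree.leaf_labels():
        raise TreeError(f"species {species!r} not in tree")
    rng = _rng_of(seed)
    from .incongruence import attachment_context

    achieved: dict[int, list[tuple[frozenset[str], Tree]]] = {}
    for dest in _candidate_destinations(tree, species):
        cand = _regraft_leaf(tree, species, dest)
        d = node_displacement(tree, cand, species)
        achieved.setdefault(d, []).append((dest, cand))
    if target_displacement not in achieved:
        raise ValueError(
            f"displacement {target_displacement} unreachable for "
            f"{species!r}; achievable values: {sorted(achieved)}")
    options = sorted(achieved[target_displacement],
                     key=lambda kv: tuple(sorted(kv[0])))
    dest, derived = options[int(rng.integers(len(options)))]
    event = CaptureEvent(
        species=species,
        source_siblings=tuple(sorted(
            attachment_context(tree, species).sibling_set)),
        destination_clade=tuple(sorted(dest)),
        displacement=target_displacement,
    )
    return derived, event


# ---------------------------------------------------------------------------
# posterior emulation


def _internal_unrooted_edges(tree: Tree) -> list[Node]:
    """Child nodes representing internal edges of the unrooted tree.

    For a degree-2 root, the two root edges form one unrooted edge,
    represented once (by the first internal root child).
    """
    edges = []
    root = tree.root
    deg2 = not root.is_leaf and len(root.children) == 2
    root_done = False
    for node in tree.postorder():
        if node.is_leaf or node is root:
            continue
        if deg2 and node.parent is root:
            sibling = next(c for c in root.children if c is not node)
            if sibling.is_leaf:
                continue  # trivial split
            if root_done:
                continue
            root_done = True
            edges.append(node)
        else:
            edges.append(node)
    return edges


def _apply_nni(tree: Tree, edge_child: Node, choice: int) -> None:
    """Apply one of the three NNI resolutions at an internal edge in place.

    ``choice`` 0 keeps the topology; 1 and 2 swap one of the child's
    subtrees with a subtree from the other side of the edge.
    """
    if choice == 0:
        return
    v = edge_child
    parent = v.parent
    if parent is tree.root and len(parent.children) == 2:
        other = next(c for c in parent.children if c is not v)
        partner = other.children[0]
        swap_with_parent = other
    else:
        partner = next(c for c in parent.children if c is not v)
        swap_with_parent = parent
    mine = v.children[choice - 1]
    vi = v.children.index(mine)
    pi = swap_with_parent.children.index(partner)
    v.children[vi] = partner
    swap_with_parent.children[pi] = mine
    partner.parent = v
    mine.parent = swap_with_parent


def emulate_posterior(tree: Tree, n_samples: int, perturb_rate: float,
                      seed=0, genome_tag: str = "") -> TreeSampleSet:
    """A posterior-like tree sample around a generating topology.

    Each sample independently receives, per internal edge with probability
    ``perturb_rate``, a random NNI at that edge (uniform over the three
    resolutions, so the split survives the perturbation with probability
    1/3 when hit; expected support is ``1 - 2/3 * perturb_rate``).
    """
    if not 0.0 <= perturb_rate < 1.0:
        raise ValueError("perturb_rate must be in [0, 1)")
    rng = _rng_of(seed)
    samples = []
    n_edges = len(_internal_unrooted_edges(tree))
    for _ in range(n_samples):
        sample = tree.copy()
        hits = rng.random(n_edges) < perturb_rate
        choices = rng.integers(0, 3, size=n_edges)
        if hits.any():
            edges = _internal_unrooted_edges(sample)
            for i in np.flatnonzero(hits):
                _apply_nni(sample, edges[i], int(choices[i]))
        samples.append(sample)
    return TreeSampleSet(trees=samples, genome_tag=genome_tag)


# ---------------------------------------------------------------------------
# alignment simulation (Jukes-Cantor)


_BASES = np.array(list("ACGT"))


def simulate_alignment(tree: Tree, n_columns: int, subst_rate: float = 1.0,
                       seed=0):
    """Evolve a nucleotide alignment on a tree under Jukes-Cantor.

    Each branch receives a Poisson(rate x length) number of substitutions
    per column; each substitution moves to a uniformly chosen different
    base.  After k jumps the state is unchanged with probability
    1/4 + 3/4 (-1/3)^k, which is sampled directly.
    """
    from .parsimony import Alignment

    rng = _rng_of(seed)
    states: dict[int, np.ndarray] = {
        id(tree.root): rng.integers(0, 4, size=n_columns)
    }
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_state = states[id(node.parent)]
        length = node.length if node.length is not None else 0.0
        k = rng.poisson(subst_rate * length, size=n_columns)
        stay_p = 0.25 + 0.75 * np.power(-1.0 / 3.0, k)
        stay = rng.random(n_columns) < stay_p
        jump = (parent_state + 1 + rng.integers(0, 3, size=n_columns)) % 4
        states[id(node)] = np.where(stay, parent_state, jump)
    leaves = tree.leaves()
    return Alignment(
        taxa=[l.label for l in leaves],
        sequences=["".join(_BASES[states[id(l)]]) for l in leaves],
    )


# ---------------------------------------------------------------------------
# full scenarios


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic capture scenario.

    Defaults mirror the pipeline's study conditions: a modest section-scale
    tree, two capture events (one single-node, one multi-node), posterior
    samples of 500 trees per genome.
    """

    n_taxa: int = 16
    n_capture_events: int = 2
    displacements: tuple[int, ...] = (1, 3)
    n_samples: int = 500
    perturb_rate: float = 0.0
    accessions_per_species: int = 1
    n_columns: int = 300
    subst_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_capture_events != len(self.displacements):
            raise ValueError(
                "displacements must list one target per capture event")


@dataclass
class CaptureScenario:
    """Truth bundle: base and derived topologies, samples, events."""

    config: ScenarioConfig
    base_tree: Tree
    derived_tree: Tree
    events: list[CaptureEvent]
    samples_nuclear: TreeSampleSet
    samples_plastid: TreeSampleSet
    alignment_nuclear: "object"
    alignment_plastid: "object"
    taxon_rows: list[tuple[str, str, str]]
    multi_accession: dict[str, list[str]] = field(default_factory=dict)

    def truth_rows(self) -> list[tuple[str, int, str]]:
        from .incongruence import HYBRIDISATION_CANDIDATE, ILS_CANDIDATE

        rows = []
        for ev in self.events:
            category = (ILS_CANDIDATE if ev.displacement == 1
                        else HYBRIDISATION_CANDIDATE)
            rows.append((ev.species, ev.displacement, category))
        return rows

    def truth_tsv(self) -> str:
        lines = ["species\tdisplacement\texpected_category"]
        lines += [f"{s}\t{d}\t{c}" for s, d, c in self.truth_rows()]
        return "\n".join(lines) + "\n"


def _sibling_clade(tree: Tree, species: str) -> frozenset[str]:
    from .incongruence import attachment_context

    return attachment_context(tree, species).sibling_set


def _context_leaves(tree: Tree, species: str, shells: int = 2) -> set[str]:
    from .incongruence import attachment_context

    ctx = attachment_context(tree, species)
    out: set[str] = {species}
    for shell in ctx.shells[:shells]:
        out |= shell
    return out


def generate_scenario(config: ScenarioConfig) -> CaptureScenario:
    """Build a full scenario satisfying the identifiability constraints.

    Event species are drawn (seeded) among leaves whose sibling clade has
    at least two leaves; destination edges must subtend at least two
    leaves; successive events must not touch each other's context leaves.
    Candidate draws are retried a bounded number of times before failing.
    """
    rng = _rng_of(config.seed)
    base = derived = None
    events: list[CaptureEvent] = []
    # not every Yule draw can host every displacement set identifiably;
    # redraw the base tree (bounded, seed-derived) until placement succeeds
    for _ in range(25):
        base = simulate_species_tree(config.n_taxa, seed=rng)
        derived = base.copy()
        events = []
        used: set[str] = set()
        for target in config.displacements:
            placed = False
            labels = sorted(derived.leaf_labels())
            order = [labels[i] for i in rng.permutation(len(labels))]
            for species in order:
                if species in used:
                    continue
                sib = _sibling_clade(derived, species)
                if len(sib) < 2 or (sib & used):
                    continue
                try:
                    cand, event = _inject_constrained(
                        derived, species, target, rng, forbidden=used)
                except ValueError:
                    continue
                derived = cand
                events.append(event)
                used |= ({species} | sib | set(event.destination_clade))
                placed = True
                break
            if not placed:
                break
        if len(events) == len(config.displacements):
            break
    else:
        raise RuntimeError(
            f"could not place displacement set {config.displacements} "
            f"in a {config.n_taxa}-taxon tree (seed {config.seed})")

    base_acc, derived_acc, taxon_rows, multi = _expand_accessions(
        base, derived, config, rng)

    samples_nuc = emulate_posterior(
        base_acc, config.n_samples, config.perturb_rate,
        seed=rng, genome_tag="nrITS")
    samples_cp = emulate_posterior(
        derived_acc, config.n_samples, config.perturb_rate,
        seed=rng, genome_tag="cpDNA")
    aln_nuc = simulate_alignment(base_acc, config.n_columns,
                                 config.subst_rate, seed=rng)
    aln_cp = simulate_alignment(derived_acc, config.n_columns,
                                config.subst_rate, seed=rng)
    return CaptureScenario(
        config=config,
        base_tree=base,
        derived_tree=derived,
        events=events,
        samples_nuclear=samples_nuc,
        samples_plastid=samples_cp,
        alignment_nuclear=aln_nuc,
        alignment_plastid=aln_cp,
        taxon_rows=taxon_rows,
        multi_accession=multi,
    )


def _unambiguous(tree: Tree, cand: Tree, species: str) -> bool:
    """Is ``species`` the only single leaf whose removal reconciles the trees?

    A one-step move that merely swaps the species with a single far-side
    leaf is topologically symmetric — either leaf "moved" — so such
    candidates are rejected to keep the implanted truth identifiable.
    """
    from .consensus import bipartition_set

    labels = sorted(tree.leaf_labels())
    for z in labels:
        keep = set(labels) - {z}
        same = (bipartition_set(tree.prune_to(keep))
                == bipartition_set(cand.prune_to(keep)))
        if z == species and not same:
            return False
        if z != species and same:
            return False
    return True


def _inject_constrained(tree: Tree, species: str, target: int,
                        rng: np.random.Generator,
                        forbidden: set[str]) -> tuple[Tree, CaptureEvent]:
    achieved: dict[int, list[tuple[frozenset[str], Tree]]] = {}
    for dest in _candidate_destinations(tree, species):
        if len(dest) < 2 or (dest & forbidden):
            continue
        cand = _regraft_leaf(tree, species, dest)
        d = node_displacement(tree, cand, species)
        if d != target:
            # record reachability for the error message only
            achieved.setdefault(d, [])
            continue
        if not _unambiguous(tree, cand, species):
            continue
        achieved.setdefault(d, []).append((dest, cand))
    if target in achieved and not achieved[target]:
        del achieved[target]
    if target not in achieved:
        raise ValueError(
            f"displacement {target} unreachable under constraints; "
            f"achievable: {sorted(achieved)}")
    from .incongruence import attachment_context

    options = sorted(achieved[target], key=lambda kv: tuple(sorted(kv[0])))
    dest, derived = options[int(rng.integers(len(options)))]
    return derived, CaptureEvent(
        species=species,
        source_siblings=tuple(sorted(attachment_context(tree, species).sibling_set)),
        destination_clade=tuple(sorted(dest)),
        displacement=target,
    )


def _expand_accessions(base: Tree, derived: Tree, config: ScenarioConfig,
                       rng: np.random.Generator):
    """Emulate multi-accession terminals by splitting leaves into cherries.

    Each selected species leaf becomes k accession leaves attached by
    near-zero branches; accession labels are shared between the genomes as
    terminal names are in practice.
    """
    k = config.accessions_per_species
    moved = set()
    base_acc, derived_acc = base.copy(), derived.copy()
    taxon_rows: list[tuple[str, str, str]] = []
    multi: dict[str, list[str]] = {}
    for species in sorted(base.leaf_labels()):
        if k > 1:
            accs = [f"{species}_{i + 1}" for i in range(k)]
            multi[species] = accs
            for tree in (base_acc, derived_acc):
                leaf = tree.find_leaf(species)
                leaf.label = None
                for acc in accs:
                    leaf.add_child(Node(label=acc, length=1e-6))
        else:
            accs = [species]
        for acc in accs:
            taxon_rows.append((acc, species, "nrITS"))
            taxon_rows.append((acc, species, "cpDNA"))
    return base_acc, derived_acc, taxon_rows, multi


# ---------------------------------------------------------------------------
# writing a scenario directory


def write_scenario(scenario: CaptureScenario, outdir: str) -> None:
    """Persist a scenario as plain-text files (newick, NEXUS, FASTA, TSV)."""
    os.makedirs(outdir, exist_ok=True)

    def put(name: str, text: str) -> None:
        with open(os.path.join(outdir, name), "w") as fh:
            fh.write(text)

    put("base.nwk", write_newick(scenario.base_tree) + "\n")
    put("derived.nwk", write_newick(scenario.derived_tree) + "\n")
    put("its_samples.t", write_nexus_trees(scenario.samples_nuclear))
    put("cp_samples.t", write_nexus_trees(scenario.samples_plastid))
    for name, aln in (("alignment_A.fasta", scenario.alignment_plastid),
                      ("alignment_B.fasta", scenario.alignment_nuclear)):
        put(name, "".join(f">{t}\n{s}\n"
                          for t, s in zip(aln.taxa, aln.sequences)))
    put("taxon_map.tsv", "accession\tspecies\tgenome\n" + "".join(
        f"{a}\t{s}\t{g}\n" for a, s, g in scenario.taxon_rows))
    put("truth.tsv", scenario.truth_tsv())
    cfg = asdict(scenario.config)
    cfg["displacements"] = list(cfg["displacements"])
    put("config.json", json.dumps(cfg, indent=2) + "\n")
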