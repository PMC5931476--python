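"""Alignment handling, Fitch parsimony, tree search, and the ILD test.

The incongruence length difference (ILD) test asks whether two character
partitions (here: a chloroplast and a nuclear alignment over the same taxa)
are significantly harder to explain on a single tree than random partitions
of the pooled characters would be.  The statistic is

    D = L(A+B) - L(A) - L(B)

where L(X) is the best (most parsimonious) tree length for partition X.
The null distribution is obtained by repeatedly repartitioning the pooled
included columns, without replacement, into sets of the original sizes.
The reported p-value uses the +1/+1 correction, p = (1 + #{D_rep >= D_obs})
/ (1 + R), so finite replication never yields p = 0 (the raw proportion is
reported alongside).

Tree lengths come from Fitch small parsimony (ambiguity codes as state
sets, gaps treated as missing), with exhaustive topology enumeration for up
to 9 taxa and stepwise random addition plus NNI/SPR swapping beyond that.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from Bio import AlignIO

from .treeio import Node, Tree, TreeError

__all__ = [
    "Alignment",
    "SearchSettings",
    "ILDResult",
    "read_alignment",
    "apply_exclusion_ranges",
    "count_parsimony_informative",
    "fitch_length",
    "enumerate_unrooted_topologies",
    "parsimony_search",
    "ild_test",
]

# IUPAC nucleotide codes as bitmasks over (A, C, G, T); gaps and unknowns
# are treated as missing data (the full state set), so an all-gap column
# contributes no changes
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "U": 8}
_IUPAC = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}
_STATE_OF: dict[str, int] = {}
for _b, _v in _BASE_BITS.items():
    _STATE_OF[_b] = _v
for _amb, _bases in _IUPAC.items():
    _STATE_OF[_amb] = sum(_BASE_BITS[x] for x in _bases)
for _miss in ("N", "X", "?", "-", "."):
    _STATE_OF[_miss] = 15

_UNAMBIGUOUS = {"A", "C", "G", "T", "U"}


@dataclass
class Alignment:
    """Equal-length sequences with a per-column inclusion mask.

    Column coordinates are 1-based and inclusive everywhere, matching how
    exclusion ranges are reported in practice (e.g. "bases 494-548").
    """

    taxa: list[str]
    sequences: list[str]
    included: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValueError("one sequence per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = {t for t in self.taxa if self.taxa.count(t) > 1}
            raise ValueError(f"duplicate taxa: {sorted(dupes)}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        if self.included is None:
            self.included = np.ones(self.n_columns, dtype=bool)
        else:
            self.included = np.asarray(self.included, dtype=bool)
            if self.included.shape != (self.n_columns,):
                raise ValueError("inclusion mask length mismatch")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def state_matrix(self, included_only: bool = True) -> np.ndarray:
        """(n_taxa, n_cols) uint8 matrix of state-set bitmasks."""
        mat = np.zeros((self.n_taxa, self.n_columns), dtype=np.uint8)
        for i, seq in enumerate(self.sequences):
            for j, ch in enumerate(seq):
                try:
                    mat[i, j] = _STATE_OF[ch]
                except KeyError:
                    raise ValueError(
                        f"unrecognised character {ch!r} at row {self.taxa[i]!r}, "
                        f"column {j + 1}")
        if included_only:
            mat = mat[:, self.included]
        return mat

    def subset_taxa(self, keep: Sequence[str]) -> "Alignment":
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in keep if t not in index]
        if missing:
            raise ValueError(f"taxa not in alignment: {missing}")
        return Alignment(
            taxa=list(keep),
            sequences=[self.sequences[index[t]] for t in keep],
            included=self.included.copy(),
        )


def read_alignment(text: str, format: str = "fasta") -> Alignment:
    """Read a FASTA or NEXUS alignment (interleaved NEXUS supported)."""
    fmt = format.lower()
    if fmt not in {"fasta", "nexus"}:
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        aln = AlignIO.read(io.StringIO(text), fmt)
    except Exception as exc:
        raise ValueError(f"could not parse {fmt} alignment: {exc}") from exc
    return Alignment(taxa=[rec.id for rec in aln],
                     sequences=[str(rec.seq) for rec in aln])


def read_alignment_file(path: str) -> Alignment:
    with open(path) as fh:
        text = fh.read()
    fmt = "nexus" if text.lstrip().lower().startswith("#nexus") else "fasta"
    return read_alignment(text, format=fmt)


def apply_exclusion_ranges(aln: Alignment,
                           ranges: Sequence[tuple[int, int]]) -> Alignment:
    """Exclude 1-based inclusive column intervals from all computations.

    Original coordinates are retained (the mask is flipped in place on a
    copy), so reports can still refer to the source positions.
    """
    mask = aln.included.copy()
    for start, end in ranges:
        if start > end:
            raise ValueError(f"inverted exclusion interval {start}-{end}")
        if start < 1 or end > aln.n_columns:
            raise ValueError(
                f"exclusion interval {start}-{end} outside 1-{aln.n_columns}")
        mask[start - 1:end] = False
    return Alignment(taxa=list(aln.taxa), sequences=list(aln.sequences),
                     included=mask)


def parse_exclusion_spec(spec: str) -> list[tuple[int, int]]:
    """Parse an exclusion string such as ``"494-548, 1-10"``."""
    ranges = []
    for chunk in spec.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "-" in chunk:
            lo, hi = chunk.split("-", 1)
            ranges.append((int(lo), int(hi)))
        else:
            ranges.append((int(chunk), int(chunk)))
    return ranges


def count_parsimony_informative(aln: Alignment) -> tuple[int, int]:
    """(included column count, parsimony-informative count).

    A column is informative iff at least two distinct unambiguous states
    each occur in at least two taxa; gaps and ambiguity codes never count
    as states.
    """
    informative = 0
    cols = np.array([list(s) for s in aln.sequences])
    for j in np.flatnonzero(aln.included):
        col = cols[:, j]
        states, counts = np.unique(
            [c for c in col if c in _UNAMBIGUOUS], return_counts=True)
        if (counts >= 2).sum() >= 2:
            informative += 1
    return aln.n_included, informative


# ---------------------------------------------------------------------------
# Fitch parsimony


def _merge_program(tree: Tree, taxon_index: dict[str, int]) -> list[tuple[int, int, int]]:
    """Compile a binary tree into postorder merge instructions.

    Leaves occupy slots [0, n); each instruction (i, j, k) merges slots i
    and j into slot k.  Polytomies must be resolved beforehand.
    """
    n = len(taxon_index)
    program: list[tuple[int, int, int]] = []
    next_slot = n
    slot: dict[int, int] = {}
    work = tree.resolve_polytomies()
    # fold a trifurcating root into a binary one for the program
    while len(work.root.children) > 2:
        a = work.root.children[-2]
        b = work.root.children[-1]
        work.root.remove_child(a)
        work.root.remove_child(b)
        joint = Node()
        joint.add_child(a)
        joint.add_child(b)
        work.root.add_child(joint)
    for node in work.postorder():
        if node.is_leaf:
            if node.label not in taxon_index:
                raise TreeError(f"tree leaf {node.label!r} not in alignment")
            slot[id(node)] = taxon_index[node.label]
        else:
            acc = slot[id(node.children[0])]
            for child in node.children[1:]:
                program.append((acc, slot[id(child)], next_slot))
                acc = next_slot
                next_slot += 1
            slot[id(node)] = acc
    return program


def _fitch_changes(program: list[tuple[int, int, int]],
                   states: np.ndarray) -> np.ndarray:
    """Per-column Fitch change counts for one merge program.

    ``states``: (n_taxa, n_cols) uint8 bitmask matrix.
    """
    n_slots = len(states) + len(program)
    buf = np.empty((n_slots, states.shape[1]), dtype=np.uint8)
    buf[: len(states)] = states
    changes = np.zeros(states.shape[1], dtype=np.int64)
    for i, j, k in program:
        inter = buf[i] & buf[j]
        empty = inter == 0
        changes += empty
        buf[k] = np.where(empty, buf[i] | buf[j], inter)
    return changes


def fitch_length(tree: Tree, aln: Alignment) -> int:
    """Minimum number of state changes of the alignment on the tree.

    Summed over included columns only; polytomies are resolved
    deterministically first (zero extra cost under Fitch counting relative
    to the best resolution is *not* guaranteed for polytomies, so callers
    wanting exact lengths should pass binary trees).
    """
    if set(tree.leaf_labels()) != set(aln.taxa):
        raise TreeError(
            "tree leaves and alignment taxa differ: "
            f"{sorted(set(tree.leaf_labels()) ^ set(aln.taxa))}")
    taxon_index = {t: i for i, t in enumerate(aln.taxa)}
    program = _merge_program(tree, taxon_index)
    states = aln.state_matrix()
    if states.shape[1] == 0:
        return 0
    return int(_fitch_changes(program, states).sum())


# ---------------------------------------------------------------------------
# topology enumeration (unrooted binary trees)


def _rooted_shapes(leaves: tuple[int, ...]) -> Iterator:
    """All rooted binary tree shapes over an ordered leaf tuple.

    Generated by inserting each successive leaf into every edge (including
    above the root) of every smaller tree; (2m-3)!! shapes for m leaves.
    """
    if len(leaves) == 1:
        yield leaves[0]
        return
    for sub in _rooted_shapes(leaves[:-1]):
        new = leaves[-1]
        for t in _insert_everywhere(sub, new):
            yield t


def _insert_everywhere(tree, leaf) -> Iterator:
    yield (tree, leaf)  # above the current root
    if isinstance(tree, tuple):
        left, right = tree
        for t in _insert_everywhere(left, leaf):
            yield (t, right)
        for t in _insert_everywhere(right, leaf):
            yield (left, t)


def enumerate_unrooted_topologies(taxa: Sequence[str]) -> Iterator[Tree]:
    """All (2n-5)!! unrooted binary topologies over ``taxa`` (n >= 3).

    Each unrooted tree is produced rooted at the internal node adjacent to
    the first taxon, which downstream split-based code treats as unrooted.
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")

    def build(shape) -> Node:
        if isinstance(shape, int):
            return Node(label=taxa[shape])
        node = Node()
        node.add_child(build(shape[0]))
        node.add_child(build(shape[1]))
        return node

    if len(taxa) == 3:
        root = Node()
        for t in taxa:
            root.add_child(Node(label=t))
        yield Tree(root)
        return
    for shape in _rooted_shapes(tuple(range(1, len(taxa)))):
        root = Node()
        root.add_child(Node(label=taxa[0]))
        if isinstance(shape, int):
            root.add_child(build(shape))
        else:
            root.add_child(build(shape[0]))
            root.add_child(build(shape[1]))
        yield Tree(root)


def _n_unrooted(n: int) -> int:
    out = 1
    for k in range(3, n + 1):
        out *= max(2 * k - 5, 1)
    return out


# ---------------------------------------------------------------------------
# search


@dataclass
class SearchSettings:
    """Heuristic search settings, recorded verbatim in ILD reports."""

    n_random_addition: int = 10
    swap: str = "NNI"
    maxtrees: int = 100
    seed: int = 0
    exact_limit: int = 9  # exhaustive enumeration at or below this many taxa


def _tree_key(tree: Tree) -> frozenset:
    from .consensus import bipartition_set

    return frozenset(bipartition_set(tree))


def parsimony_search(aln: Alignment,
                     settings: SearchSettings | None = None) -> tuple[int, list[Tree]]:
    """Best parsimony length and the best trees found (up to ``maxtrees``).

    Exact (exhaustive over all unrooted topologies) for small taxon sets;
    otherwise stepwise random addition with branch swapping to a local
    optimum, deterministic given the seed.
    """
    settings = settings or SearchSettings()
    if aln.n_taxa < 4:
        raise ValueError("parsimony search needs at least 4 taxa")
    taxon_index = {t: i for i, t in enumerate(aln.taxa)}
    states = aln.state_matrix()
    if aln.n_taxa <= settings.exact_limit:
        best_len = None
        best_trees: list[Tree] = []
        for tree in enumerate_unrooted_topologies(aln.taxa):
            length = int(_fitch_changes(
                _merge_program(tree, taxon_index), states).sum())
            if best_len is None or length < best_len:
                best_len, best_trees = length, [tree]
            elif length == best_len and len(best_trees) < settings.maxtrees:
                best_trees.append(tree)
        return best_len, best_trees
    return _heuristic_search(aln, states, taxon_index, settings)


def _length_of(tree: Tree, states: np.ndarray, taxon_index: dict[str, int]) -> int:
    return int(_fitch_changes(_merge_program(tree, taxon_index), states).sum())


def _attach_positions(tree: Tree) -> list[Node]:
    return [n for n in tree.postorder() if n is not tree.root]


def _attach_leaf(tree: Tree, edge_child: Node, label: str) -> Tree:
    out = tree.copy()
    # locate the corresponding node in the copy by postorder position
    originals = list(tree.postorder())
    copies = list(out.postorder())
    target = copies[originals.index(edge_child)]
    parent = target.parent
    mid = Node()
    idx = parent.children.index(target)
    parent.children[idx] = mid
    mid.parent = parent
    mid.add_child(target)
    mid.add_child(Node(label=label))
    return out

def _nni_neighbours(tree: Tree) -> Iterator[Tree]:
    """All trees one nearest-neighbour interchange away."""
    nodes = list(tree.postorder())
    for idx, node in enumerate(nodes):
        if node.is_leaf or node is tree.root or node.parent is None:
            continue
        parent = node.parent
        siblings = [c for c in parent.children if c is not node]
        if not siblings or parent is tree.root and len(parent.children) == 2 \
                and all(s.is_leaf for s in siblings):
            continue
        for ci in range(len(node.children)):
            for si in range(len(siblings)):
                out = tree.copy()
                out_nodes = list(out.postorder())
                n2 = out_nodes[idx]
                p2 = n2.parent
                sib2 = [c for c in p2.children if c is not n2][si]
                ch2 = n2.children[ci]
                # swap ch2 and sib2
                n2.children[ci] = sib2
                p2.children[p2.children.index(sib2)] = ch2
                sib2.parent, ch2.parent = n2, p2
                yield out


def _spr_neighbours(tree: Tree) -> Iterator[Tree]:
    """Subtree-prune-and-regraft neighbours (leaf and clade moves)."""
    nodes = list(tree.postorder())
    for idx, node in enumerate(nodes):
        if node is tree.root or node.parent is tree.root and len(tree.root.children) <= 2:
            continue
        prune_labels = {l.label for l in Tree(node).leaves()}
        if len(prune_labels) >= len(tree.leaf_labels()) - 2:
            continue
        base = tree.copy()
        base_nodes = list(base.postorder())
        sub = base_nodes[idx]
        parent = sub.parent
        parent.remove_child(sub)
        base.suppress_unary()
        base.suppress_root_degree2()
        for edge_child in list(base.postorder()):
            if edge_child is base.root:
                continue
            out = base.copy()
            o_nodes = list(base.postorder())
            c_nodes = list(out.postorder())
            target = c_nodes[o_nodes.index(edge_child)]
            tparent = target.parent
            mid = Node()
            j = tparent.children.index(target)
            tparent.children[j] = mid
            mid.parent = tparent
            mid.add_child(target)
            mid.add_child(_copy_subtree(sub))
            yield out


def _copy_subtree(node: Node) -> Node:
    new = Node(node.label, node.length, node.support, node.ic)
    for child in node.children:
        new.add_child(_copy_subtree(child))
    return new


def _heuristic_search(aln: Alignment, states: np.ndarray,
                      taxon_index: dict[str, int],
                      settings: SearchSettings) -> tuple[int, list[Tree]]:
    rng = np.random.default_rng(settings.seed)
    neighbour_fn = {"NNI": _nni_neighbours, "SPR": _spr_neighbours}.get(
        settings.swap.upper())
    if neighbour_fn is None:
        raise ValueError(f"unknown swap set {settings.swap!r}; use NNI or SPR")
    best_len: int | None = None
    best_trees: list[Tree] = []
    best_keys: set[frozenset] = set()
    for _ in range(settings.n_random_addition):
        order = [aln.taxa[i] for i in rng.permutation(aln.n_taxa)]
        root = Node()
        for lab in order[:3]:
            root.add_child(Node(label=lab))
        tree = Tree(root)
        for lab in order[3:]:
            sub = aln.subset_taxa(sorted(set(
                [l.label for l in tree.leaves()] + [lab])))
            sub_states = sub.state_matrix()
            sub_index = {t: i for i, t in enumerate(sub.taxa)}
            candidates = [
                _attach_leaf(tree, pos, lab) for pos in _attach_positions(tree)
            ]
            lengths = [_length_of(c, sub_states, sub_index) for c in candidates]
            tree = candidates[int(np.argmin(lengths))]
        # swap to a local optimum
        cur_len = _length_of(tree, states, taxon_index)
        improved = True
        while improved:
            improved = False
            for nb in neighbour_fn(tree):
                l = _length_of(nb, states, taxon_index)
                if l < cur_len:
                    tree, cur_len = nb, l
                    improved = True
                    break
        if best_len is None or cur_len < best_len:
            best_len = cur_len
            best_trees = [tree]
            best_keys = {_tree_key(tree)}
        elif cur_len == best_len:
            key = _tree_key(tree)
            if key not in best_keys and len(best_trees) < settings.maxtrees:
                best_trees.append(tree)
                best_keys.add(key)
    return best_len, best_trees


# ---------------------------------------------------------------------------
# ILD test


@dataclass
class ILDResult:
    """Observed incongruence length difference and its permutation null."""

    d_observed: int
    replicate_d: list[int]
    p_value: float          # (1 + #{D_rep >= D_obs}) / (1 + R)
    p_raw: float            # #{D_rep >= D_obs} / R
    replicates: int
    seed: int
    settings: SearchSettings
    lengths: dict[str, int] = field(default_factory=dict)
    dropped_taxa: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        import json

        reps = np.asarray(self.replicate_d)
        return json.dumps({
            "d_observed": self.d_observed,
            "p_value": self.p_value,
            "p_raw": self.p_raw,
            "replicates": self.replicates,
            "seed": self.seed,
            "lengths": self.lengths,
            "replicate_summary": {
                "min": int(reps.min()), "max": int(reps.max()),
                "mean": float(reps.mean()),
            },
            "settings": {
                "n_random_addition": self.settings.n_random_addition,
                "swap": self.settings.swap,
                "maxtrees": self.settings.maxtrees,
                "exact_limit": self.settings.exact_limit,
            },
            "dropped_taxa": self.dropped_taxa,
        }, indent=2)

    def replicates_tsv(self) -> str:
        lines = ["replicate\td"]
        lines += [f"{i + 1}\t{d}" for i, d in enumerate(self.replicate_d)]
        return "\n".join(lines) + "\n"


def _per_tree_column_lengths(taxa: list[str], states: np.ndarray) -> np.ndarray:
    """(n_topologies, n_cols) Fitch lengths for all unrooted topologies.

    Duplicate column patterns are evaluated once and scattered back.
    """
    taxon_index = {t: i for i, t in enumerate(taxa)}
    packed = np.ascontiguousarray(states.T)
    uniq, inverse = np.unique(packed, axis=0, return_inverse=True)
    uniq_states = np.ascontiguousarray(uniq.T)
    rows = []
    for tree in enumerate_unrooted_topologies(taxa):
        program = _merge_program(tree, taxon_index)
        rows.append(_fitch_changes(program, uniq_states))
    per_unique = np.asarray(rows)
    return per_unique[:, inverse]


def ild_test(
    aln_a: Alignment,
    aln_b: Alignment,
    replicates: int = 100,
    settings: SearchSettings | None = None,
    seed: int = 0,
) -> ILDResult:
    """Permutation ILD test between two alignments over shared taxa.

    Taxa missing from either partition are dropped (recorded on the
    result).  Only included columns enter the pooled character set.  For
    taxon sets within the exact-search limit, the per-topology, per-column
    length matrix is computed once, making observed and replicate searches
    exact subset sums.
    """
    settings = settings or SearchSettings(seed=seed)
    shared = sorted(set(aln_a.taxa) & set(aln_b.taxa))
    dropped = sorted(set(aln_a.taxa) ^ set(aln_b.taxa))
    if len(shared) < 4:
        raise ValueError(f"ILD test needs >= 4 shared taxa, got {len(shared)}")
    sub_a = aln_a.subset_taxa(shared)
    sub_b = aln_b.subset_taxa(shared)
    states_a = sub_a.state_matrix()
    states_b = sub_b.state_matrix()
    pooled = np.concatenate([states_a, states_b], axis=1)
    n_a = states_a.shape[1]
    n_total = pooled.shape[1]
    rng = np.random.default_rng(seed)

    if len(shared) <= settings.exact_limit:
        M = _per_tree_column_lengths(shared, pooled)

        def best_length(cols: np.ndarray) -> int:
            return int(M[:, cols].sum(axis=1).min())

        l_comb = int(M.sum(axis=1).min())
        l_a = best_length(np.arange(n_a))
        l_b = best_length(np.arange(n_a, n_total))
        d_obs = l_comb - l_a - l_b
        replicate_d = []
        for _ in range(replicates):
            perm = rng.permutation(n_total)
            ra = best_length(perm[:n_a])
            rb = best_length(perm[n_a:])
            replicate_d.append(l_comb - ra - rb)
    else:
        def run_search(states: np.ndarray) -> int:
            aln = Alignment(taxa=shared,
                            sequences=_states_to_sequences(states))
            length, _ = parsimony_search(aln, settings)
            return length

        l_comb = run_search(pooled)
        l_a = run_search(states_a)
        l_b = run_search(states_b)
        d_obs = l_comb - l_a - l_b
        replicate_d = []
        for _ in range(replicates):
            perm = rng.permutation(n_total)
            ra = run_search(pooled[:, perm[:n_a]])
            rb = run_search(pooled[:, perm[n_a:]])
            replicate_d.append(l_comb - ra - rb)

    n_ge = sum(1 for d in replicate_d if d >= d_obs)
    return ILDResult(
        d_observed=d_obs,
        replicate_d=replicate_d,
        p_value=(1 + n_ge) / (1 + replicates),
        p_raw=n_ge / replicates if replicates else float("nan"),
        replicates=replicates,
        seed=seed,
        settings=settings,
        lengths={"combined": l_comb, "partition_a": l_a, "partition_b": l_b},
        dropped_taxa=dropped,
    )


_BITS_TO_CHAR = {v: k for k, v in _STATE_OF.items() if k not in "UX?.-"}
_BITS_TO_CHAR[15] = "N"


def _states_to_sequences(states: np.ndarray) -> list[str]:
    return ["".join(_BITS_TO_CHAR[int(v)] for v in row) for row in states]
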