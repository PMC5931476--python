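"""Reading, writing and managing populations of phylogenetic trees.

Trees arrive either as plain Newick lists (one ``;``-terminated tree per
line) or as NEXUS ``trees`` blocks with an optional ``translate`` table, the
dialect written by Bayesian MCMC samplers such as MrBayes (``tree gen.N =
[&U] (...)``).  Parsing is delegated to :mod:`dendropy`; parsed trees are
converted into a small mutable :class:`Tree` structure on which the rest of
the package operates.

Trees are stored rooted (a parent/child structure) but every downstream
computation treats them as unrooted: consensus, internode certainty and
conflict detection are all defined on bipartitions, and the rooting of MCMC
output is arbitrary.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "TreeError",
    "TreeParseError",
    "Node",
    "Tree",
    "TreeSampleSet",
    "parse_newick",
    "parse_newick_list",
    "parse_nexus_trees",
    "read_tree_samples",
    "apply_burnin",
    "write_newick",
    "write_nexus_trees",
]


class TreeError(ValueError):
    """Invalid tree structure or invalid operation on a tree."""


class TreeParseError(TreeError):
    """Raised when a tree document cannot be parsed."""


_NUMBER_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


class Node:
    """A node of a rooted tree.

    ``label`` is the taxon name for leaves; for internal nodes it is only
    used as a fallback carrier for support values found in that position.
    ``support`` is a posterior proportion in [0, 1]; ``ic`` an internode
    certainty in [0, 1]; both refer to the edge above the node.
    """

    __slots__ = ("label", "length", "support", "ic", "children", "parent")

    def __init__(self, label=None, length=None, support=None, ic=None):
        self.label: str | None = label
        self.length: float | None = length
        self.support: float | None = support
        self.ic: float | None = ic
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label!r} nchild={len(self.children)}>"


class Tree:
    """A leaf-labelled tree with optional edge lengths and edge supports."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> set[str]:
        return {n.label for n in self.leaves()}

    def internal_nodes(self, exclude_root: bool = True) -> list[Node]:
        out = []
        for n in self.postorder():
            if n.is_leaf:
                continue
            if exclude_root and n is self.root:
                continue
            out.append(n)
        return out

    def find_leaf(self, label: str) -> Node:
        for n in self.postorder():
            if n.is_leaf and n.label == label:
                return n
        raise TreeError(f"leaf {label!r} not present in tree")

    # -- structure ---------------------------------------------------------

    def copy(self) -> "Tree":
        def _copy(node: Node) -> Node:
            new = Node(node.label, node.length, node.support, node.ic)
            for child in node.children:
                new.add_child(_copy(child))
            return new

        return Tree(_copy(self.root), rooted=self.rooted)

    def validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        if not labels:
            raise TreeError("tree has no leaves")
        seen = set()
        for lab in labels:
            if lab is None or lab == "":
                raise TreeError("tree contains an unlabelled leaf")
            if lab in seen:
                raise TreeError(f"duplicate leaf label {lab!r}")
            seen.add(lab)
        for n in self.postorder():
            if not n.is_leaf and len(n.children) == 1:
                raise TreeError("tree contains a unary internal node")
            if n.length is not None and n.length < 0:
                raise TreeError(f"negative edge length {n.length} on {n.label!r}")

    def suppress_unary(self, support_merge: Callable[[float, float], float] = max) -> None:
        """Remove internal nodes with a single child, summing edge lengths.

        When an edge above and below a suppressed node both carry support,
        the merged edge keeps ``support_merge`` of the two (default: max,
        appropriate when both original edges induce the same restricted
        bipartition).
        """
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if node.is_leaf or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                if node.support is not None and child.support is not None:
                    child.support = support_merge(node.support, child.support)
                elif child.support is None:
                    child.support = node.support
                if child.ic is None:
                    child.ic = node.ic
                if node is self.root:
                    child.parent = None
                    self.root = child
                else:
                    parent = node.parent
                    idx = parent.children.index(node)
                    parent.children[idx] = child
                    child.parent = parent
                changed = True

    def suppress_root_degree2(self) -> None:
        """Merge the two edges of a degree-2 root into one (unrooted view)."""
        while not self.root.is_leaf and len(self.root.children) == 2:
            a, b = self.root.children
            if a.is_leaf and b.is_leaf:
                break  # a 2-leaf tree cannot be collapsed further
            keep, move = (a, b) if not a.is_leaf else (b, a)
            self.root.remove_child(keep)
            self.root.remove_child(move)
            if keep.length is not None or move.length is not None:
                move.length = (keep.length or 0.0) + (move.length or 0.0)
            if move.support is None:
                move.support = keep.support
            if move.ic is None:
                move.ic = keep.ic
            keep.length = None
            keep.support = None
            keep.ic = None
            keep.add_child(move)
            self.root = keep
            keep.parent = None

    def prune_to(self, keep: Iterable[str],
                 support_merge: Callable[[float, float], float] = max) -> "Tree":
        """Induced subtree on the leaf set ``keep``.

        Unary nodes created by the pruning are suppressed with branch
        lengths summed across them.
        """
        keep = set(keep)
        missing = keep - self.leaf_labels()
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        if len(keep) < 3:
            raise TreeError("cannot prune to fewer than 3 leaves")
        out = self.copy()
        for leaf in list(out.leaves()):
            if leaf.label not in keep:
                _remove_leaf(out, leaf)
        out.suppress_unary(support_merge=support_merge)
        return out

    def reroot_at_leaf(self, label: str) -> "Tree":
        """A copy re-rooted so the named leaf hangs directly off the root.

        The unrooted topology is unchanged; every split not containing the
        leaf becomes a rooted clade.  Edge annotations follow their edge
        when parent/child direction flips.
        """
        work = self.copy()
        leaf = work.find_leaf(label)
        parent = leaf.parent
        if parent is None or parent is work.root:
            work.suppress_unary()
            return work
        chain: list[Node] = []
        node = parent
        while node is not None:
            chain.append(node)
            node = node.parent
        # chain = [new root, ..., old root]; detach then reverse each edge
        old_ann = {id(n): (n.length, n.support, n.ic) for n in chain}
        for i in range(len(chain) - 1):
            chain[i + 1].remove_child(chain[i])
        for i in range(len(chain) - 1):
            child, par = chain[i], chain[i + 1]
            child.add_child(par)
            par.length, par.support, par.ic = old_ann[id(child)]
        root = chain[0]
        root.length = root.support = root.ic = None
        root.parent = None
        work.root = root
        work.suppress_unary()  # the old root may be left unary
        return work

    def resolve_polytomies(self) -> "Tree":
        """Return a binary copy; polytomies resolved left-to-right (caterpillar).

        The resolution is arbitrary but deterministic: children beyond the
        first are folded pairwise into zero-length nodes.
        """
        out = self.copy()
        for node in list(out.postorder()):
            while len(node.children) > 2:
                a = node.children[-2]
                b = node.children[-1]
                node.remove_child(a)
                node.remove_child(b)
                joint = Node(length=0.0)
                joint.add_child(a)
                joint.add_child(b)
                node.add_child(joint)
        if len(out.root.children) == 3:
            # keep an unrooted-style trifurcating root; callers wanting a
            # strictly binary rooted tree fold it themselves
            pass
        return out

    def __len__(self) -> int:
        return len(self.leaves())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree n_leaves={len(self)}>"


def _remove_leaf(tree: Tree, leaf: Node) -> None:
    parent = leaf.parent
    if parent is None:
        raise TreeError("cannot remove the only node of a tree")
    parent.remove_child(leaf)
    # parent may now be unary (or empty, for malformed input); leave the
    # unary suppression to the caller so annotations merge once
    if not parent.children and parent.parent is not None:
        _remove_leaf(tree, parent)


@dataclass
class TreeSampleSet:
    """An ordered population of trees from one analysis (one genome).

    Order is preserved from the source file because burn-in is a prefix
    operation on the MCMC sample sequence.
    """

    trees: list[Tree]
    genome_tag: str = ""
    burnin_applied: bool = False
    source: str | None = None

    def __post_init__(self) -> None:
        if self.trees:
            universe = self.trees[0].leaf_labels()
            for i, t in enumerate(self.trees):
                if t.leaf_labels() != universe:
                    diff = t.leaf_labels() ^ universe
                    raise TreeError(
                        f"tree {i} has a different leaf set; symmetric "
                        f"difference: {sorted(diff)}"
                    )

    def leaf_labels(self) -> set[str]:
        if not self.trees:
            return set()
        return self.trees[0].leaf_labels()

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[Tree]:
        return iter(self.trees)

    def prune_to(self, keep: Iterable[str]) -> "TreeSampleSet":
        keep = set(keep)
        return TreeSampleSet(
            trees=[t.prune_to(keep) for t in self.trees],
            genome_tag=self.genome_tag,
            burnin_applied=self.burnin_applied,
            source=self.source,
        )


# ---------------------------------------------------------------------------
# parsing


def _support_from_dendropy(nd: "dendropy.Node") -> float | None:
    # internal-node-label position first, then comment position; the first
    # numeric value wins (both dialects occur in the wild)
    if nd.label is not None:
        m = _NUMBER_RE.fullmatch(nd.label.strip())
        if m:
            return float(m.group(0))
    for comment in nd.comments or []:
        m = _NUMBER_RE.search(comment)
        if m:
            return float(m.group(0))
    if nd.edge is not None:
        for comment in nd.edge.comments or []:
            m = _NUMBER_RE.search(comment)
            if m:
                return float(m.group(0))
    return None


def _ic_from_dendropy(nd: "dendropy.Node") -> float | None:
    for holder in ([nd] + ([nd.edge] if nd.edge is not None else [])):
        for comment in holder.comments or []:
            m = re.search(r"ic\s*=\s*([-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)", comment)
            if m:
                return float(m.group(1))
    return None


def _convert_dendropy(dtree: "dendropy.Tree") -> Tree:
    def conv(nd: "dendropy.Node") -> Node:
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            node = Node(label=label, length=nd.edge.length)
        else:
            node = Node(length=nd.edge.length)
            node.support = _support_from_dendropy(nd)
            node.ic = _ic_from_dendropy(nd)
            for ch in nd.child_nodes():
                node.add_child(conv(ch))
        return node

    tree = Tree(conv(dtree.seed_node), rooted=bool(dtree.is_rooted))
    tree.suppress_unary()
    tree.validate()
    return tree


def parse_newick(text: str) -> Tree:
    """Parse a single Newick string into a :class:`Tree`.

    Polytomies are preserved; labels, branch lengths and a single numeric
    support value (in internal-node-label or comment position) are
    retained.  Raises :class:`TreeParseError` on malformed input,
    identifying the position when the backend reports one.
    """
    text = text.strip()
    if not text:
        raise TreeParseError("empty tree string")
    if not text.endswith(";"):
        raise TreeParseError(
            f"Newick string must end with ';' (offset {len(text)})"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeParseError(f"malformed Newick: {exc}") from exc
    try:
        return _convert_dendropy(dtree)
    except TreeError as exc:
        raise TreeParseError(str(exc)) from exc


def parse_newick_list(text: str) -> list[Tree]:
    """Parse a document of one-per-line ``;``-terminated Newick trees."""
    trees = []
    for chunk in text.split(";"):
        if chunk.strip():
            trees.append(parse_newick(chunk + ";"))
    if not trees:
        raise TreeParseError("no trees found in Newick document")
    return trees


def parse_nexus_trees(text: str, genome_tag: str = "",
                      source: str | None = None) -> TreeSampleSet:
    """Parse a NEXUS ``trees`` block into a :class:`TreeSampleSet`.

    Numeric tip tokens are replaced via the ``translate`` table when one is
    present; trees are returned in file order.
    """
    if "begin trees" not in text.lower():
        raise TreeParseError("NEXUS document contains no trees block")
    _check_translate_tokens(text)
    try:
        dtrees = dendropy.TreeList.get(
            data=text, schema="nexus", preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:
        raise TreeParseError(f"malformed NEXUS trees block: {exc}") from exc
    if not dtrees:
        raise TreeParseError("NEXUS trees block contains no tree statements")
    trees = [_convert_dendropy(t) for t in dtrees]
    return TreeSampleSet(trees=trees, genome_tag=genome_tag, source=source)


def _check_translate_tokens(text: str) -> None:
    # dendropy silently treats unknown numeric tokens as new taxa; the
    # contract here is an error that names the offending token
    m = re.search(r"translate\s+(.*?);", text, flags=re.IGNORECASE | re.DOTALL)
    if not m:
        return
    table: set[str] = set()
    for entry in m.group(1).split(","):
        parts = entry.split()
        if parts:
            table.add(parts[0].strip())
    if not table:
        return
    for tm in re.finditer(r"^\s*tree\s+\S+\s*=\s*(.*?);", text,
                          flags=re.IGNORECASE | re.MULTILINE | re.DOTALL):
        stmt = re.sub(r"\[.*?\]", "", tm.group(1))
        for tok in re.finditer(r"[(,]\s*(\d+)\s*[:,)]", stmt):
            if tok.group(1) not in table:
                raise TreeParseError(
                    f"tip token {tok.group(1)!r} absent from translate table"
                )


def read_tree_samples(path: str, genome_tag: str = "") -> TreeSampleSet:
    """Read tree samples from a file, sniffing Newick list vs NEXUS."""
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().lower().startswith("#nexus"):
        return parse_nexus_trees(text, genome_tag=genome_tag, source=path)
    trees = parse_newick_list(text)
    return TreeSampleSet(trees=trees, genome_tag=genome_tag, source=path)


# ---------------------------------------------------------------------------
# burn-in


def apply_burnin(samples: TreeSampleSet, fraction: float) -> TreeSampleSet:
    """Drop the first ``floor(fraction * N)`` trees of an MCMC sample.

    The study default discards the first 25% of sampled trees.  Applying
    burn-in twice is refused to guard against a double discard.
    """
    if not samples.trees:
        raise TreeError("cannot apply burn-in to an empty sample set")
    if samples.burnin_applied:
        raise TreeError("burn-in has already been applied to this sample set")
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"burn-in fraction must be in [0, 1), got {fraction}")
    n_drop = int(fraction * len(samples.trees))
    return TreeSampleSet(
        trees=samples.trees[n_drop:],
        genome_tag=samples.genome_tag,
        burnin_applied=True,
        source=samples.source,
    )


# ---------------------------------------------------------------------------
# writing

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


def _format_label(label: str) -> str:
    if "'" in label:
        raise TreeError(f"label {label!r} contains a quote and cannot be written")
    if _NEWICK_UNSAFE.search(label):
        return f"'{label}'"
    return label


def write_newick(tree: Tree, include_support: bool = True,
                 include_lengths: bool = True, include_ic: bool = False) -> str:
    """Serialise a tree to Newick.

    Support and IC go into a comment annotation on internal edges
    (``[&support=0.75,ic=0.19]``) which :func:`parse_newick` reads back.
    Round-trips preserve leaf set, topology and retained annotations.
    """

    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = _format_label(node.label)
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            ann = []
            if include_support and node.support is not None:
                ann.append(f"support={node.support:.6g}")
            if include_ic and node.ic is not None:
                ann.append(f"ic={node.ic:.4f}")
            if ann:
                s += "[&" + ",".join(ann) + "]"
        if include_lengths and node.length is not None:
            s += f":{node.length:.10g}"
        return s

    return fmt(tree.root) + ";"


def write_nexus_trees(samples: TreeSampleSet, include_lengths: bool = True) -> str:
    """Write a sample set as a NEXUS trees block with a translate table."""
    labels = sorted(samples.leaf_labels())
    index = {lab: str(i + 1) for i, lab in enumerate(labels)}
    buf = io.StringIO()
    buf.write("#NEXUS\n\nbegin trees;\n    translate\n")
    buf.write(",\n".join(f"        {i + 1} {_format_label(lab)}"
                         for i, lab in enumerate(labels)))
    buf.write(";\n")
    for k, tree in enumerate(samples.trees):
        t = tree.copy()
        for leaf in t.leaves():
            leaf.label = index[leaf.label]
        nwk = write_newick(t, include_support=False,
                           include_lengths=include_lengths)
        buf.write(f"    tree sample.{k + 1} = [&U] {nwk}\n")
    buf.write("end;\n")
    return buf.getvalue()
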