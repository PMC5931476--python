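"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from phylodiscord.treeio import Tree, parse_newick


@pytest.fixture
def quartet() -> Tree:
    return parse_newick("((A,B),(C,D));")


def random_tree(n_leaves: int, rng: np.random.Generator) -> Tree:
    """A random unrooted-binary topology built by sequential edge insertion."""
    from phylodiscord.treeio import Node

    labels = [f"L{i}" for i in range(n_leaves)]
    root = Node()
    for lab in labels[:3]:
        root.add_child(Node(label=lab))
    tree = Tree(root)
    for lab in labels[3:]:
        edges = [n for n in tree.postorder() if n is not tree.root]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        mid = Node()
        idx = parent.children.index(target)
        parent.children[idx] = mid
        mid.parent = parent
        mid.add_child(target)
        mid.add_child(Node(label=lab))
    return tree


# ---------------------------------------------------------------------------
# independent split oracle (graph edge-cut via networkx)


def edge_cut_splits(tree: Tree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial splits of a tree found by cutting every edge of its graph.

    Deliberately independent of the package's bipartition code: the tree is
    converted to a networkx graph, each edge removed in turn, and the leaf
    labels of the two connected components collected.
    """
    g = nx.Graph()
    label_of = {}
    for node in tree.postorder():
        g.add_node(id(node))
        if node.is_leaf:
            label_of[id(node)] = node.label
        for child in node.children:
            g.add_edge(id(node), id(child))
    leaves = set(label_of)
    out = set()
    for u, v in list(g.edges):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        g.add_edge(u, v)
        side_a = frozenset(label_of[n] for n in comp & leaves)
        side_b = frozenset(label_of[n] for n in leaves - comp)
        if len(side_a) >= 2 and len(side_b) >= 2:
            out.add(frozenset((side_a, side_b)))
    return out


def splitset(tree: Tree) -> set[frozenset[frozenset[str]]]:
    """Package bipartitions re-expressed in the oracle's neutral encoding."""
    from phylodiscord.consensus import bipartition_set

    return {
        frozenset((b.mask, b.complement)) for b in bipartition_set(tree)
    }


# ---------------------------------------------------------------------------
# independent Fitch oracle (exhaustive internal-state assignment)


def brute_force_length(tree: Tree, columns: np.ndarray,
                       taxa: list[str]) -> np.ndarray:
    """Minimum changes per column by enumerating all internal assignments.

    ``columns``: (n_taxa, n_cols) integer states in 0..3.  Returns the
    per-column minima.  Only valid for trees small enough that 4**n_internal
    assignments fit in memory.
    """
    internal = [n for n in tree.postorder() if not n.is_leaf]
    index = {id(n): i for i, n in enumerate(internal)}
    taxon_row = {t: i for i, t in enumerate(taxa)}
    k = len(internal)
    assign = np.array(list(itertools.product(range(4), repeat=k)))  # (4^k, k)
    n_cols = columns.shape[1]
    cost = np.zeros((assign.shape[0], n_cols), dtype=np.int32)
    for node in tree.postorder():
        if node is tree.root:
            continue
        parent_states = assign[:, index[id(node.parent)]]
        if node.is_leaf:
            leaf_states = columns[taxon_row[node.label]]  # (n_cols,)
            cost += parent_states[:, None] != leaf_states[None, :]
        else:
            mismatch = parent_states != assign[:, index[id(node)]]
            cost += mismatch[:, None]
    return cost.min(axis=0)
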