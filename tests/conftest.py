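"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own path computations:
tree distances come from networkx shortest paths on the explicit tree
graph, and bipartitions from connected components after removing each edge.
"""

from __future__ import annotations

import dendropy
import networkx as nx
import numpy as np
import pytest


def tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def tree_graph(t: dendropy.Tree, weighted: bool = False) -> nx.Graph:
    """Explicit graph of a dendropy tree (nodes keyed by id)."""
    g = nx.Graph()
    for node in t.preorder_node_iter():
        g.add_node(id(node), label=node.taxon.label if node.taxon else None)
        if node.parent_node is not None:
            w = node.edge.length if weighted else 1.0
            g.add_edge(id(node.parent_node), id(node), weight=w)
    return g


def leaf_ids(t: dendropy.Tree) -> dict[str, int]:
    return {leaf.taxon.label: id(leaf) for leaf in t.leaf_node_iter()}


def oracle_path_edges(t: dendropy.Tree, a: str, b: str) -> int:
    """Edge count on the a-b path by breadth-first search on the graph."""
    g = tree_graph(t)
    ids = leaf_ids(t)
    return nx.shortest_path_length(g, ids[a], ids[b])


def oracle_bipartitions(t: dendropy.Tree) -> set[frozenset[str]]:
    """Every edge's induced leaf bipartition, via connected components
    after removing that edge; each split is the side without the smallest
    label."""
    g = tree_graph(t)
    labels = {data["label"] for _, data in g.nodes(data=True) if data["label"]}
    ref = min(labels)
    splits = set()
    for u, v in list(g.edges()):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        side = frozenset(
            g.nodes[n]["label"] for n in comp if g.nodes[n]["label"] is not None
        )
        g.add_edge(u, v)
        if 0 < len(side) < len(labels):
            splits.add(side if ref not in side else frozenset(labels - side))
    return splits


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
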