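"""Pairwise topological distances between the leaves of a tree.

The response variable of the distance-matrix regression is *node distance*:
the number of internal nodes on the path between two leaves, so that sister
taxa (a cherry) are at node distance 1.  Equivalently it is the path length
in edges minus one.  Rooting matters: the root is an internal node on every
path that crosses it, so a rooted caterpillar ((((A,B),C),D)) puts A and D
at node distance 3 while the unrooted topology puts them at 2.  Trees are
measured AS ROOTED in the input unless ``unroot=True`` collapses a
bifurcating root first.

Patristic distance (sum of branch lengths along the path) is offered as an
alternative response for trees with reliable branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrixError",
    "DistanceMatrix",
    "node_distance_matrix",
    "patristic_distance_matrix",
]


class DistanceMatrixError(ValueError):
    """Invalid distance matrix or distance computation input."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled square symmetric matrix with zero diagonal.

    Parameters
    ----------
    labels : tuple of str
        Taxon labels in canonical order (shared by all matrices of one
        analysis).
    values : ndarray of shape (n, n)
        Nonnegative finite distances; symmetric with zero diagonal.
    units : str
        Units tag, conventionally ``"nodes"``, ``"meters"``,
        ``"kilometers"`` or ``"model-units"``.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    units: str = "model-units"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if n < 2:
            raise DistanceMatrixError("need at least 2 taxa")
        if len(set(self.labels)) != n:
            raise DistanceMatrixError("taxon labels must be unique")
        if values.shape != (n, n):
            raise DistanceMatrixError(
                f"values shape {values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(values)):
            raise DistanceMatrixError("distance entries must be finite")
        if not np.allclose(values, values.T, rtol=0.0, atol=1e-9):
            raise DistanceMatrixError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(values)) > 1e-12):
            raise DistanceMatrixError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Return a copy with rows/columns in the given label order."""
        labels = tuple(labels)
        if set(labels) != set(self.labels) or len(labels) != self.n:
            raise DistanceMatrixError(
                "reorder labels must be a permutation of the matrix labels"
            )
        idx = [self.labels.index(lab) for lab in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)], self.units)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        """Long-format pairs (taxon_i, taxon_j, value) for i < j."""
        rows = [
            (self.labels[i], self.labels[j], self.values[i, j])
            for i in range(self.n)
            for j in range(i + 1, self.n)
        ]
        return pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "value"])

    def write_tsv(self, path: str | Path) -> None:
        """Tab-delimited square matrix with header row and label column."""
        self.to_dataframe().to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def read_tsv(cls, path: str | Path, units: str = "model-units") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise DistanceMatrixError(f"{path}: row and column labels differ")
        return cls(tuple(df.index), df.to_numpy(dtype=float), units)


# -- path computations -------------------------------------------------------


def _leaf_paths(tree: dendropy.Tree, weighted: bool):
    """Per-leaf (depth, ancestor-chain) from an explicit rooted traversal.

    Returns (labels, edge_depth, weight_depth, parent, leaf_nodes_index)
    where depths are measured from the seed (root) node.
    """
    root = tree.seed_node
    depth_edges: dict[int, int] = {id(root): 0}
    depth_w: dict[int, float] = {id(root): 0.0}
    parent: dict[int, Optional[dendropy.Node]] = {id(root): None}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        p = node.parent_node
        parent[id(node)] = p
        depth_edges[id(node)] = depth_edges[id(p)] + 1
        if weighted:
            if node.edge.length is None:
                label = node.taxon.label if node.taxon else "<internal>"
                raise DistanceMatrixError(
                    f"missing branch length on edge above {label}"
                )
            if node.edge.length < 0:
                raise DistanceMatrixError("negative branch length")
            depth_w[id(node)] = depth_w[id(p)] + node.edge.length
    return depth_edges, depth_w, parent


def _pairwise(tree: dendropy.Tree, weighted: bool) -> tuple[list[str], np.ndarray]:
    depth_edges, depth_w, parent = _leaf_paths(tree, weighted)
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    if len(set(labels)) != len(labels):
        raise DistanceMatrixError("duplicate leaf labels")
    n = len(labels)
    out = np.zeros((n, n), dtype=float)
    depth = depth_w if weighted else depth_edges
    for i in range(n):
        for j in range(i + 1, n):
            a, b = leaves[i], leaves[j]
            da, db = depth_edges[id(a)], depth_edges[id(b)]
            # climb to equal edge-depth, then in lockstep to the LCA
            while da > db:
                a = parent[id(a)]
                da -= 1
            while db > da:
                b = parent[id(b)]
                db -= 1
            while a is not b:
                a, b = parent[id(a)], parent[id(b)]
            lca = a
            d = depth[id(leaves[i])] + depth[id(leaves[j])] - 2 * depth[id(lca)]
            out[i, j] = out[j, i] = d
    return labels, out


def _prepare_tree(tree: dendropy.Tree, unroot: bool) -> dendropy.Tree:
    work = tree.clone(depth=1)
    if unroot:
        # collapse a bifurcating (or singleton) root so it no longer
        # counts as an internal node on paths crossing it
        work.suppress_unifurcations()
        if len(work.seed_node.child_nodes()) == 2:
            work.collapse_basal_bifurcation()
        work.is_rooted = False
    return work


def node_distance_matrix(
    tree: dendropy.Tree,
    label_order: Optional[Sequence[str]] = None,
    unroot: bool = False,
) -> DistanceMatrix:
    """Topological node-distance matrix: internal nodes per leaf-pair path.

    Entry (i, j) counts the internal nodes on the path between leaves i and
    j (path length in edges minus 1); a cherry is at distance 1 and the
    diagonal is 0.  With ``unroot=True`` a bifurcating root is collapsed
    before counting, so the root no longer separates the two sides.
    """
    work = _prepare_tree(tree, unroot)
    labels, edges = _pairwise(work, weighted=False)
    values = edges.copy()
    off = ~np.eye(len(labels), dtype=bool)
    values[off] -= 1.0
    dm = DistanceMatrix(tuple(labels), values, units="nodes")
    order = tuple(label_order) if label_order is not None else tuple(sorted(labels))
    return dm.reorder(order)


def patristic_distance_matrix(
    tree: dendropy.Tree,
    label_order: Optional[Sequence[str]] = None,
) -> DistanceMatrix:
    """Patristic distances: sum of branch lengths along each leaf-pair path."""
    work = _prepare_tree(tree, unroot=False)
    labels, values = _pairwise(work, weighted=True)
    dm = DistanceMatrix(tuple(labels), values, units="model-units")
    order = tuple(label_order) if label_order is not None else tuple(sorted(labels))
    return dm.reorder(order)
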