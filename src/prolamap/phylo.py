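"""Average-distance (UPGMA) trees from pairwise identities.

The clustering that separates prolamin sequences into their protein
groups assumes a molecular clock, so the tree is built by classic UPGMA
rather than neighbour joining: repeatedly merge the closest pair of
clusters at height d_min / 2 and replace their distances to the rest by
size-weighted arithmetic means.  The result is an ultrametric rooted
binary tree whose cophenetic distance between two leaves equals twice
the height of their lowest common ancestor.

Distances here are identity distances, d = 100 - percent identity, so
branch lengths are in identity-percent units (a deliberate, documented
departure from substitutions-per-site scales): the tree is read for its
topology — which sequences cluster into which group — not for its
branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")


@dataclass
class TreeNode:
    """Rooted binary tree node; leaves have height 0 and a label."""

    height: float
    label: str | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]


def distances_from_identity(labels: Sequence[str], identity: np.ndarray) -> DistanceMatrix:
    """Convert a percent-identity matrix to identity distances d = 100 - id,
    clipped to [0, 100]."""
    identity = np.asarray(identity, dtype=float)
    if not np.allclose(identity, identity.T):
        raise ValueError("identity matrix must be symmetric")
    d = np.clip(100.0 - identity, 0.0, 100.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(labels), d)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Build the UPGMA tree.

    Merges the pair with the minimal distance at height d_min / 2; the
    merged cluster's distance to any other cluster is the size-weighted
    mean of its parts.  Ties take the smallest (row, column) index pair
    in current label order; the merged cluster occupies the smaller
    index.  Deterministic.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 labels")

    nodes: list[TreeNode] = [TreeNode(0.0, label=lab) for lab in dm.labels]
    sizes: list[int] = [1] * n
    d = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 1:
        best: tuple[float, int, int] | None = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                dij = d[active[ai], active[aj]]
                if best is None or dij < best[0] - 1e-15:
                    best = (dij, ai, aj)
        dij, ai, aj = best
        i, j = active[ai], active[aj]
        height = dij / 2.0
        merged = TreeNode(height, children=(nodes[i], nodes[j]))
        si, sj = sizes[i], sizes[j]
        # size-weighted average linkage update, stored at slot i
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (si * d[i, k] + sj * d[j, k]) / (si + sj)
        nodes[i] = merged
        sizes[i] = si + sj
        active.pop(aj)

    return nodes[active[0]]


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def to_newick(tree: TreeNode) -> str:
    """Newick string with branch lengths = parent height - child height."""

    def render(node: TreeNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{_fmt(length)}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{_fmt(length)}"

    if tree.is_leaf:
        return f"{tree.label};"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    return f"({inner});"


def cut_clusters(tree: TreeNode, height: float) -> list[list[str]]:
    """Partition leaves into the connected groups joined below ``height``.

    A subtree whose merge height is <= ``height`` forms one cluster;
    cutting at 0 yields singletons.
    """
    if height < 0:
        raise ValueError("cut height must be non-negative")
    clusters: list[list[str]] = []

    def descend(node: TreeNode) -> None:
        if node.height <= height:
            clusters.append(node.leaf_labels())
        else:
            for c in node.children:
                descend(c)

    descend(tree)
    return clusters


def cophenetic_matrix(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Cophenetic distances: 2 x height of the lowest common ancestor."""
    labels = tree.leaf_labels()
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n))

    def visit(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.label]
        sides = [visit(c) for c in node.children]
        for a in sides[0]:
            for b in sides[1]:
                out[index[a], index[b]] = out[index[b], index[a]] = 2.0 * node.height
        return sides[0] + sides[1]

    visit(tree)
    return labels, out
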