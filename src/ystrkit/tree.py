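"""Neighbor-joining trees from population distance matrices, plus Newick.

Saitou–Nei agglomeration with the standard Q-criterion.  The build is
bit-reproducible: tied Q values are broken by the lexicographically
smallest label pair, internal nodes are numbered in creation order, and
Newick children are sorted by their smallest descendant leaf label.
Negative branch-length estimates are clipped to zero with the excess
transferred to the sibling edge.  Negative input distances (slightly
negative Phi-st) are clipped to zero up front.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = ["neighbor_joining", "write_newick", "tree_leaves"]

log = logging.getLogger(__name__)


def tree_leaves(tree: nx.Graph) -> list[str]:
    return sorted(n for n, d in tree.nodes(data=True) if d.get("kind") == "leaf")


def neighbor_joining(labels: Sequence[str], distances: np.ndarray) -> nx.Graph:
    """Build an unrooted NJ tree; returns a graph with 'length' edge attrs.

    Leaves carry ``kind='leaf'``; internal nodes ``kind='internal'``.
    For m leaves (m >= 3) the tree has m - 2 internal nodes.
    """
    labels = [str(l) for l in labels]
    D0 = np.asarray(distances, dtype=float)
    m = len(labels)
    if D0.shape != (m, m):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D0, D0.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if len(set(labels)) != m:
        raise ValueError("duplicate labels")
    if m < 2:
        raise ValueError("need at least 2 taxa")
    neg = int((D0 < 0).sum())
    if neg:
        log.info("clipping %d negative distances to 0 before NJ", neg)
    D0 = np.where(D0 < 0, 0.0, D0)

    tree = nx.Graph()
    for l in labels:
        tree.add_node(l, kind="leaf")

    d: dict[tuple[str, str], float] = {}

    def get(i: str, j: str) -> float:
        return d[(i, j)] if (i, j) in d else d[(j, i)]

    for (ii, a), (jj, b) in combinations(enumerate(labels), 2):
        d[(a, b)] = float(D0[ii, jj])

    active = sorted(labels)
    counter = 0

    if m == 2:
        a, b = active
        counter += 1
        u = f"node{counter}"
        tree.add_node(u, kind="internal")
        half = get(a, b) / 2.0
        tree.add_edge(a, u, length=half)
        tree.add_edge(b, u, length=half)
        tree.graph["root"] = u
        return tree

    def clip_pair(li: float, lj: float) -> tuple[float, float]:
        # clip a negative estimate at 0, moving the excess to the sibling
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        k = len(active)
        r = {i: sum(get(i, j) for j in active if j != i) for i in active}
        best = None
        best_q = np.inf
        for a, b in combinations(active, 2):  # active is sorted -> lexicographic
            q = (k - 2) * get(a, b) - r[a] - r[b]
            if q < best_q - 1e-15:
                best_q, best = q, (a, b)
        a, b = best
        dab = get(a, b)
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (k - 2))
        lb = dab - la
        la, lb = clip_pair(la, lb)
        counter += 1
        u = f"node{counter}"
        tree.add_node(u, kind="internal")
        tree.add_edge(a, u, length=la)
        tree.add_edge(b, u, length=lb)
        for c in active:
            if c in (a, b):
                continue
            d[(u, c)] = 0.5 * (get(a, c) + get(b, c) - dab)
        active = sorted([c for c in active if c not in (a, b)] + [u])

    # final three nodes join at one central vertex
    x, y, z = active
    counter += 1
    u = f"node{counter}"
    tree.add_node(u, kind="internal")
    lx = 0.5 * (get(x, y) + get(x, z) - get(y, z))
    ly = 0.5 * (get(x, y) + get(y, z) - get(x, z))
    lz = 0.5 * (get(x, z) + get(y, z) - get(x, y))
    for node, length in ((x, lx), (y, ly), (z, lz)):
        tree.add_edge(node, u, length=max(length, 0.0))
    tree.graph["root"] = u
    return tree


def _min_leaf(tree: nx.Graph, node: str, parent: str | None) -> str:
    if tree.nodes[node].get("kind") == "leaf":
        return node
    return min(
        _min_leaf(tree, c, node) for c in tree.neighbors(node) if c != parent
    )


def _newick_rec(tree: nx.Graph, node: str, parent: str | None) -> str:
    children = sorted(
        (c for c in tree.neighbors(node) if c != parent),
        key=lambda c: _min_leaf(tree, c, node),
    )
    if not children:
        return node
    parts = []
    for c in children:
        length = tree.edges[node, c]["length"]
        parts.append(f"{_newick_rec(tree, c, node)}:{length:g}")
    inner = ",".join(parts)
    return f"({inner})"


def write_newick(tree: nx.Graph, root: str | None = None) -> str:
    """Serialize an (unrooted) tree to Newick, rooted for display.

    The root defaults to the tree's recorded central node, else the
    first internal node in sorted order.
    """
    leaves = tree_leaves(tree)
    if len(leaves) != len(set(leaves)):
        raise ValueError("duplicate leaf labels")
    if root is None:
        root = tree.graph.get("root")
    if root is None:
        internal = sorted(
            n for n, d in tree.nodes(data=True) if d.get("kind") == "internal"
        )
        root = internal[0] if internal else leaves[0]
    return _newick_rec(tree, root, None) + ";"
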