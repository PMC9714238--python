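"""Median-joining haplotype networks over Y-STR repeat vectors.

The construction follows the classic three stages for multistate
(ordered) STR data:

1. *condense*: identical repeat vectors collapse to one node carrying a
   multiplicity and per-population composition;
2. *minimum spanning network*: keep every edge whose length does not
   exceed the bottleneck (minimax-path) distance between its endpoints
   plus a relaxation parameter epsilon — at epsilon 0 this is the union
   of all minimum spanning trees, at large epsilon the complete graph;
3. *median augmentation*: for connected node triples, the per-locus
   median vector is added as an inferred (multiplicity-0) node whenever
   it is new and connecting the triple through it is cheaper than the
   triple's own spanning edges; iterate to a fixed point, then prune
   inferred nodes that end up as dead ends.

Edge lengths default to the sum of absolute repeat differences (number
of single-step mutations separating two haplotypes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .markers import NETWORK_LOCI_14, PopulationSample, to_repeat_vector

__all__ = [
    "CondensedHaplotype",
    "HaplotypeNetwork",
    "condense",
    "msn",
    "add_medians",
    "mj_network",
    "export_network",
    "import_network",
]


@dataclass(frozen=True)
class CondensedHaplotype:
    """A distinct repeat vector with its observed multiplicity."""

    vector: tuple[float, ...]
    multiplicity: int
    composition: tuple[tuple[str, int], ...] = ()  # (population, count)

    @property
    def inferred(self) -> bool:
        return self.multiplicity == 0


def condense(
    samples: Iterable[PopulationSample],
    loci: Sequence[str] = NETWORK_LOCI_14,
) -> list[CondensedHaplotype]:
    """Collapse identical repeat vectors, accumulating multiplicities."""
    acc: dict[tuple[float, ...], dict[str, int]] = {}
    for sample in samples:
        for h in sample.haplotypes:
            vec = to_repeat_vector(h, loci)
            comp = acc.setdefault(vec, {})
            comp[sample.label] = comp.get(sample.label, 0) + 1
    out = []
    for vec in sorted(acc):
        comp = acc[vec]
        out.append(
            CondensedHaplotype(
                vector=vec,
                multiplicity=sum(comp.values()),
                composition=tuple(sorted(comp.items())),
            )
        )
    return out


def _dist(u: Sequence[float], v: Sequence[float], metric: str) -> float:
    a = np.asarray(u, dtype=float)
    b = np.asarray(v, dtype=float)
    if metric == "l1":
        return float(np.abs(a - b).sum())
    if metric == "squared":
        return float(((a - b) ** 2).sum())
    raise ValueError(f"unknown network metric {metric!r}")


@dataclass(frozen=True)
class HaplotypeNetwork:
    """Graph of observed + inferred haplotype nodes keyed by repeat vector."""

    graph: nx.Graph
    loci: tuple[str, ...]
    epsilon: float
    metric: str = "l1"

    @property
    def nodes(self) -> list[CondensedHaplotype]:
        return [
            CondensedHaplotype(
                vector=v,
                multiplicity=d["multiplicity"],
                composition=tuple(tuple(c) for c in d["composition"]),
            )
            for v, d in sorted(self.graph.nodes(data=True))
        ]

    @property
    def total_multiplicity(self) -> int:
        return sum(d["multiplicity"] for _, d in self.graph.nodes(data=True))


def _edge_steps(
    u: tuple[float, ...], v: tuple[float, ...], loci: Sequence[str]
) -> str:
    steps = []
    for locus, a, b in zip(loci, u, v):
        if a != b:
            steps.append(f"{locus}:{b - a:+g}")
    return ";".join(steps)


def _bottlenecks(nodes: list[tuple[float, ...]], D: np.ndarray) -> np.ndarray:
    """Minimax path distance for every pair, via max edge on the MST path."""
    n = len(nodes)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in combinations(range(n), 2):
        g.add_edge(i, j, weight=D[i, j])
    mst = nx.minimum_spanning_tree(g, weight="weight")
    bn = np.zeros((n, n))
    for src in range(n):
        # DFS from src over MST tracking the running max edge weight
        stack = [(src, -1, 0.0)]
        while stack:
            node, parent, running = stack.pop()
            for nb in mst.neighbors(node):
                if nb == parent:
                    continue
                w = max(running, mst.edges[node, nb]["weight"])
                bn[src, nb] = w
                stack.append((nb, node, w))
    return bn


def msn(
    nodes: Sequence[CondensedHaplotype],
    metric: str = "l1",
    epsilon: float = 0.0,
    loci: Sequence[str] = NETWORK_LOCI_14,
) -> HaplotypeNetwork:
    """Epsilon-relaxed minimum spanning network over condensed haplotypes."""
    if not nodes:
        raise ValueError("need at least one node")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    nodes = sorted(nodes, key=lambda c: c.vector)
    vecs = [c.vector for c in nodes]
    if len(set(vecs)) != len(vecs):
        raise ValueError("duplicate vectors among condensed haplotypes")
    g = nx.Graph()
    for c in nodes:
        g.add_node(
            c.vector, multiplicity=c.multiplicity, composition=list(c.composition)
        )
    n = len(nodes)
    if n > 1:
        X = np.asarray(vecs, dtype=float)
        diff = X[:, None, :] - X[None, :, :]
        if metric == "l1":
            D = np.abs(diff).sum(axis=2)
        elif metric == "squared":
            D = (diff ** 2).sum(axis=2)
        else:
            raise ValueError(f"unknown network metric {metric!r}")
        bn = _bottlenecks(vecs, D)
        for i, j in combinations(range(n), 2):
            if D[i, j] <= bn[i, j] + epsilon + 1e-12:
                g.add_edge(
                    vecs[i],
                    vecs[j],
                    weight=float(D[i, j]),
                    steps=_edge_steps(vecs[i], vecs[j], loci),
                )
    return HaplotypeNetwork(
        graph=g, loci=tuple(loci), epsilon=float(epsilon), metric=metric
    )


def _is_int(x: float) -> bool:
    return abs(x - round(x)) < 1e-9


def _median_vector(
    u: tuple[float, ...], v: tuple[float, ...], w: tuple[float, ...]
) -> tuple[float, ...] | None:
    """Coordinate-wise median of three vectors.

    Integer repeat states take the true median; if any of the three
    values at a locus is a microvariant, the majority value is used and
    a three-way tie vetoes the whole candidate.
    """
    med = []
    for a, b, c in zip(u, v, w):
        if _is_int(a) and _is_int(b) and _is_int(c):
            med.append(float(sorted((a, b, c))[1]))
        elif a == b or a == c:
            med.append(a)
        elif b == c:
            med.append(b)
        else:
            return None
    return tuple(med)


def _candidate_triples(g: nx.Graph) -> list[tuple]:
    """Connected triples: both (u,v) and (v,w) are current edges."""
    triples = set()
    for v in g.nodes:
        for u, w in combinations(sorted(g.neighbors(v)), 2):
            triples.add(tuple(sorted((u, v, w))))
    return sorted(triples)


def add_medians(net: HaplotypeNetwork, max_new: int | None = None) -> HaplotypeNetwork:
    """One round of median augmentation; returns a rebuilt network.

    New inferred nodes are accepted when the Steiner star through the
    median is cheaper than the triple's own minimum spanning edges.
    """
    g = net.graph
    existing = set(g.nodes)
    new: list[tuple[float, ...]] = []
    for u, v, w in _candidate_triples(g):
        m = _median_vector(u, v, w)
        if m is None or m in existing or m in new:
            continue
        duv = _dist(u, v, net.metric)
        duw = _dist(u, w, net.metric)
        dvw = _dist(v, w, net.metric)
        star = sum(_dist(x, m, net.metric) for x in (u, v, w))
        mst_cost = duv + duw + dvw - max(duv, duw, dvw)
        if star < mst_cost - 1e-12:
            new.append(m)
            if max_new is not None and len(new) >= max_new:
                break
    if not new:
        return net
    nodes = net.nodes + [
        CondensedHaplotype(vector=m, multiplicity=0) for m in sorted(new)
    ]
    return msn(nodes, metric=net.metric, epsilon=net.epsilon, loci=net.loci)


def _prune_dead_medians(net: HaplotypeNetwork) -> HaplotypeNetwork:
    g = net.graph.copy()
    while True:
        dead = [
            v
            for v, d in g.nodes(data=True)
            if d["multiplicity"] == 0 and g.degree(v) <= 1
        ]
        if not dead:
            break
        g.remove_nodes_from(dead)
    return replace(net, graph=g)


def mj_network(
    samples: Iterable[PopulationSample],
    epsilon: float = 0.0,
    metric: str = "l1",
    loci: Sequence[str] = NETWORK_LOCI_14,
    max_rounds: int = 50,
) -> HaplotypeNetwork:
    """Full median-joining construction from population samples."""
    nodes = condense(samples, loci)
    net = msn(nodes, metric=metric, epsilon=epsilon, loci=loci)
    for _ in range(max_rounds):
        grown = add_medians(net)
        if grown is net:
            return _prune_dead_medians(net)
        net = grown
    raise RuntimeError(
        f"median augmentation did not stabilize within {max_rounds} rounds "
        f"({net.graph.number_of_nodes()} nodes, "
        f"{net.graph.number_of_edges()} edges)"
    )


def export_network(net: HaplotypeNetwork, fmt: str = "gml") -> str:
    """Serialize to GML text with multiplicity, composition and edge steps."""
    if fmt != "gml":
        raise ValueError("only 'gml' export is supported")
    g = nx.Graph()
    g.graph["epsilon"] = net.epsilon
    g.graph["metric"] = net.metric
    g.graph["loci"] = ",".join(net.loci)
    index = {v: i for i, v in enumerate(sorted(net.graph.nodes))}
    for v, i in index.items():
        d = net.graph.nodes[v]
        g.add_node(
            i,
            vector=",".join(f"{x:g}" for x in v),
            multiplicity=int(d["multiplicity"]),
            composition=json.dumps(dict(d["composition"] or [])),
        )
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(index[u], index[v], weight=float(d["weight"]),
                   steps=d.get("steps", ""))
    return "\n".join(nx.generate_gml(g)) + "\n"


def import_network(text: str) -> HaplotypeNetwork:
    """Inverse of :func:`export_network`."""
    g0 = nx.parse_gml(text.splitlines(), label="id")
    loci = tuple(g0.graph["loci"].split(","))
    g = nx.Graph()
    mapping = {}
    for label, d in g0.nodes(data=True):
        vec = tuple(float(x) for x in str(d["vector"]).split(","))
        comp = sorted(json.loads(d["composition"]).items())
        g.add_node(
            vec,
            multiplicity=int(d["multiplicity"]),
            composition=[(str(k), int(v)) for k, v in comp],
        )
        mapping[label] = vec
    for u, v, d in g0.edges(data=True):
        g.add_edge(
            mapping[u],
            mapping[v],
            weight=float(d["weight"]),
            steps=d.get("steps", ""),
        )
    return HaplotypeNetwork(
        graph=g,
        loci=loci,
        epsilon=float(g0.graph["epsilon"]),
        metric=g0.graph["metric"],
    )
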