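"""Molecular-complex detection by core-clustering vertex weighting (MCODE).

Each vertex is weighted by the product of the highest k-core number of its
closed neighborhood and that k-core's density.  Complexes grow greedily from
the highest-weighted unvisited seed, admitting neighbors whose weight is
within a fraction (the node score cutoff) of the seed's weight.  Predicted
complexes below the k-core filter are discarded; the optional haircut prunes
singly-connected members and fluff adds dense-neighborhood members.
Parameter defaults follow the v1.5.1 plugin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import networkx as nx

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCODEParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core_filter: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1
    max_depth: int = 100
    include_loops: bool = False

    def __post_init__(self) -> None:
        if self.degree_cutoff < 2:
            raise ValueError("degree_cutoff must be >= 2")
        if not 0.0 <= self.node_score_cutoff < 1.0:
            raise ValueError("node_score_cutoff must lie in [0, 1)")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class Cluster:
    nodes: frozenset
    seed: str
    score: float

    def __post_init__(self) -> None:
        self.nodes = frozenset(self.nodes)
        if len(self.nodes) < 2:
            raise ValueError("a cluster needs >= 2 nodes")


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def cluster_score(graph: nx.Graph, nodes) -> float:
    """density x size of the induced subgraph (the MCODE complex score)."""
    sub = graph.subgraph(nodes)
    return _density(sub) * sub.number_of_nodes()


def vertex_weights(graph: nx.Graph) -> dict:
    """Core-clustering coefficient weight for every vertex.

    w(v) = k_max x density of the highest k-core of the closed neighborhood
    N[v]; isolated vertices weigh 0.
    """
    weights = {}
    for v in graph.nodes:
        closed = set(graph.neighbors(v)) | {v}
        sub = nx.Graph(graph.subgraph(closed))
        sub.remove_edges_from(nx.selfloop_edges(sub))
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_numbers = nx.core_number(sub)
        kmax = max(core_numbers.values())
        core_nodes = [n for n, c in core_numbers.items() if c >= kmax]
        weights[v] = kmax * _density(sub.subgraph(core_nodes))
    return weights


def find_complexes(graph: nx.Graph, params: Optional[MCODEParams] = None) -> List[Cluster]:
    """Greedy complex prediction from vertex weights.

    Seeds are taken in decreasing weight (ties by node id); expansion does a
    breadth-first walk up to max_depth, admitting unvisited neighbors with
    w >= w(seed) x (1 - node_score_cutoff).  Members are marked visited, so
    complexes are node-disjoint.  Complexes whose induced subgraph lacks a
    k_core_filter-core, or with fewer than 2 nodes, are discarded.
    """
    params = params or MCODEParams()
    log.info("MCODE run with %s", params)
    g = nx.Graph(graph)
    if not params.include_loops:
        g.remove_edges_from(nx.selfloop_edges(g))
    weights = vertex_weights(g)
    order = sorted(g.nodes, key=lambda v: (-weights[v], v))
    visited: set = set()
    clusters = []
    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for u in frontier:
                for w in g.neighbors(u):
                    if w in visited:
                        continue
                    if weights[w] >= threshold:
                        visited.add(w)
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        if len(members) < 2:
            continue
        sub = g.subgraph(members)
        if max(nx.core_number(sub).values()) < params.k_core_filter:
            continue
        clusters.append(Cluster(frozenset(members), seed,
                                cluster_score(g, members)))
    clusters.sort(key=lambda c: (-c.score, c.seed))
    return clusters


def postprocess(graph: nx.Graph, clusters: List[Cluster],
                params: Optional[MCODEParams] = None) -> List[Cluster]:
    """Fluff (optional) then haircut, with scores recomputed.

    Fluff adds neighbors whose closed-neighborhood density exceeds
    fluff_density (clusters may then overlap); haircut iteratively removes
    members with fewer than two intra-cluster neighbors.  Clusters shrinking
    below 2 nodes are dropped.
    """
    params = params or MCODEParams()
    g = nx.Graph(graph)
    g.remove_edges_from(nx.selfloop_edges(g))
    out = []
    for cluster in clusters:
        members = set(cluster.nodes)
        if params.fluff:
            for v in sorted(cluster.nodes):
                for w in g.neighbors(v):
                    if w in members:
                        continue
                    closed = set(g.neighbors(w)) | {w}
                    if _density(g.subgraph(closed)) > params.fluff_density:
                        members.add(w)
        if params.haircut:
            while True:
                sub = g.subgraph(members)
                prune = {v for v in members if sub.degree(v) < 2}
                if not prune:
                    break
                members -= prune
        if len(members) < 2:
            continue
        out.append(Cluster(frozenset(members), cluster.seed,
                           cluster_score(g, members)))
    out.sort(key=lambda c: (-c.score, c.seed))
    return out


def cluster_report(graph: nx.Graph, clusters: List[Cluster],
                   net=None) -> "pd.DataFrame":
    """Cluster table: id, sizes, members, regulated / core member counts."""
    import pandas as pd

    rows = []
    for i, c in enumerate(clusters, start=1):
        sub = graph.subgraph(c.nodes)
        row = {
            "cluster": i,
            "score": c.score,
            "#nodes": sub.number_of_nodes(),
            "#edges": sub.number_of_edges(),
            "nodes": ",".join(sorted(c.nodes)),
        }
        if net is not None:
            up = sum(1 for n in c.nodes if net.nodes[n]["regulation"] == "up")
            down = sum(1 for n in c.nodes if net.nodes[n]["regulation"] == "down")
            core = sum(1 for n in c.nodes if net.nodes[n]["role"] == "core")
            row.update({"#up": up, "#down": down, "#core": core})
        rows.append(row)
    return pd.DataFrame(rows)
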