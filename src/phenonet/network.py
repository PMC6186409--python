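"""Core/first-shell protein-interaction network assembly and analysis.

The phenotype network seeds on a "core" protein set (the members of the
phenotype's pathway) and adds every protein sharing a high-confidence,
experimentally supported interaction (score >= 0.9) with a core protein (the
"first shell"), together with all qualifying interactions among the retained
proteins.  The network is a mixed multigraph: undirected binding records can
coexist with directed activation / inhibition / post-translational-modification
records between the same pair; they collapse only in the undirected simple
projection used for topology statistics and cluster detection.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Set

import networkx as nx

log = logging.getLogger(__name__)

UNDIRECTED_KINDS = frozenset({"binding"})
DIRECTED_KINDS = frozenset({"activation", "inhibition"})


@dataclass(frozen=True)
class InteractionRecord:
    node_a: str
    node_b: str
    kind: str  # "binding" | "activation" | "inhibition" | "ptm:<subtype>"
    direction: str  # "ab" | "ba" | "none"
    score: float
    evidence: str = "experimental"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")
        directed = self.kind in DIRECTED_KINDS or self.kind.startswith("ptm")
        if self.kind in UNDIRECTED_KINDS and self.direction != "none":
            raise ValueError("binding records are undirected")
        if directed and self.direction not in ("ab", "ba"):
            raise ValueError(f"{self.kind} records need direction ab or ba")
        if not directed and self.kind not in UNDIRECTED_KINDS:
            raise ValueError(f"unknown interaction kind {self.kind!r}")

    @property
    def endpoints(self) -> frozenset:
        return frozenset((self.node_a, self.node_b))

    def touches(self, node: str) -> bool:
        return node in (self.node_a, self.node_b)


def _default_attrs() -> dict:
    return {"role": "shell", "regulation": "none", "magnitude": None,
            "dna_binding": False, "drug_targets": []}


@dataclass
class PhenotypeNetwork:
    """Mixed multigraph of core + shell proteins with typed edges."""

    nodes: dict = field(default_factory=dict)  # id -> attribute dict
    edges: list = field(default_factory=list)  # InteractionRecord multiset

    def add_node(self, node: str, **attrs) -> None:
        base = self.nodes.setdefault(node, _default_attrs())
        base.update(attrs)

    def add_edge(self, rec: InteractionRecord) -> None:
        for n in (rec.node_a, rec.node_b):
            if n not in self.nodes:
                self.add_node(n)
        self.edges.append(rec)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if e.touches(node))

    def core_nodes(self) -> set:
        return {n for n, a in self.nodes.items() if a["role"] == "core"}

    def copy(self) -> "PhenotypeNetwork":
        return PhenotypeNetwork(
            nodes={n: dict(a) for n, a in self.nodes.items()},
            edges=list(self.edges),
        )

    def to_multigraph(self) -> nx.MultiGraph:
        """Underlying undirected multigraph (direction kept as edge data)."""
        g = nx.MultiGraph()
        for n, attrs in self.nodes.items():
            g.add_node(n, **attrs)
        for rec in self.edges:
            g.add_edge(rec.node_a, rec.node_b, kind=rec.kind,
                       direction=rec.direction, score=rec.score,
                       evidence=rec.evidence)
        return g


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def filter_interactions(records: Iterable[InteractionRecord],
                        min_score: float = 0.9,
                        required_evidence: Optional[str] = "experimental") -> list:
    """High-confidence records: evidence match and score >= min_score."""
    out = []
    for rec in records:
        if required_evidence is not None and rec.evidence != required_evidence:
            continue
        if rec.score >= min_score:
            out.append(rec)
    return out


def assemble_network(core: Set[str], records: Sequence[InteractionRecord]) -> PhenotypeNetwork:
    """Core + first-shell network from pre-filtered interaction records.

    Shell membership requires a qualifying record to a core protein;
    shell–shell records are kept only when both endpoints already qualified.
    Core proteins without any qualifying record remain as isolates.
    """
    core = set(core)
    if not core:
        raise ValueError("core protein set is empty")
    shell = set()
    for rec in records:
        a, b = rec.node_a, rec.node_b
        if a in core and b not in core:
            shell.add(b)
        elif b in core and a not in core:
            shell.add(a)
    keep = core | shell
    net = PhenotypeNetwork()
    for n in sorted(core):
        net.add_node(n, role="core")
    for n in sorted(shell):
        net.add_node(n, role="shell")
    for rec in records:
        if rec.node_a in keep and rec.node_b in keep:
            net.add_edge(rec)
    log.info("assembled network: %d nodes (%d core, %d shell), %d edges",
             net.n_nodes, len(core), len(shell), net.n_edges)
    return net


def remove_node(net: PhenotypeNetwork, node_id: str,
                extra_edges: Optional[Sequence[tuple]] = None) -> PhenotypeNetwork:
    """Drop a node with all incident records, plus explicitly listed edges.

    extra_edges is a list of unordered endpoint pairs; each entry removes one
    matching remaining record (used to reproduce curated removals that
    accompany a hub deletion, e.g. redundant ligase edges).
    """
    if node_id not in net.nodes:
        raise KeyError(f"node {node_id!r} not in network")
    out = net.copy()
    before = out.n_edges
    out.edges = [e for e in out.edges if not e.touches(node_id)]
    del out.nodes[node_id]
    incident = before - out.n_edges
    n_extra = 0
    for pair in extra_edges or ():
        target = frozenset(pair)
        for i, rec in enumerate(out.edges):
            if rec.endpoints == target:
                del out.edges[i]
                n_extra += 1
                break
        else:
            warnings.warn(f"extra edge {tuple(pair)} not found")
    log.info("removed %s: %d incident + %d curated edges; now %d nodes, %d edges",
             node_id, incident, n_extra, out.n_nodes, out.n_edges)
    return out


def connected_components(net: PhenotypeNetwork) -> list:
    """Components as sub-networks, largest first.

    Ordering: node count desc, then edge count desc, then smallest node id.
    """
    g = net.to_multigraph()
    comps = []
    for nodes in nx.connected_components(g):
        sub = PhenotypeNetwork(
            nodes={n: dict(net.nodes[n]) for n in nodes},
            edges=[e for e in net.edges if e.node_a in nodes],
        )
        comps.append(sub)
    comps.sort(key=lambda c: (-c.n_nodes, -c.n_edges, min(c.nodes)))
    return comps


def core_shell_split(net: PhenotypeNetwork) -> tuple:
    """(core_net, shell_net): core-induced edges vs everything else.

    The two edge lists partition the full edge multiset exactly; the shell
    part keeps every edge with at least one shell endpoint plus its incident
    nodes.
    """
    core = net.core_nodes()
    core_edges = [e for e in net.edges if e.node_a in core and e.node_b in core]
    shell_edges = [e for e in net.edges
                   if not (e.node_a in core and e.node_b in core)]
    core_net = PhenotypeNetwork(
        nodes={n: dict(a) for n, a in net.nodes.items() if n in core},
        edges=core_edges,
    )
    shell_nodes = set()
    for e in shell_edges:
        shell_nodes |= {e.node_a, e.node_b}
    shell_net = PhenotypeNetwork(
        nodes={n: dict(net.nodes[n]) for n in shell_nodes},
        edges=shell_edges,
    )
    return core_net, shell_net


def induce_subnetwork(net: PhenotypeNetwork, members: Iterable[str]) -> PhenotypeNetwork:
    """Subgraph induced on the network nodes belonging to a term's gene union.

    Members isolated inside the induced subgraph are retained — in figures
    such proteins connect to the rest of the parent network.
    """
    members = set(members) & set(net.nodes)
    if not members:
        warnings.warn("term union does not intersect the network")
    return PhenotypeNetwork(
        nodes={n: dict(net.nodes[n]) for n in members},
        edges=[e for e in net.edges
               if e.node_a in members and e.node_b in members],
    )


def annotate(net: PhenotypeNetwork, calls: Optional[Mapping] = None,
             dna_binding: Optional[Set[str]] = None,
             drug_targets: Optional[Mapping[str, Set[str]]] = None) -> PhenotypeNetwork:
    """Overlay regulation, DNA-binding and drug-target annotations.

    calls maps gene -> ("up"/"down"/"none", log2 fold change) or a pandas
    frame with "final" and "magnitude" columns; unmatched nodes keep
    regulation "none".
    """
    out = net.copy()
    if calls is not None and hasattr(calls, "iterrows"):
        calls = {g: (row["final"], row.get("magnitude")) for g, row in calls.iterrows()}
    for node, attrs in out.nodes.items():
        if calls and node in calls:
            final, magnitude = calls[node]
            attrs["regulation"] = final
            if magnitude is not None and magnitude == magnitude:  # not NaN
                attrs["magnitude"] = float(magnitude)
        if dna_binding is not None:
            attrs["dna_binding"] = node in dna_binding
    if drug_targets:
        for drug, targets in drug_targets.items():
            for node in targets:
                if node in out.nodes:
                    out.nodes[node]["drug_targets"] = sorted(
                        set(out.nodes[node]["drug_targets"]) | {drug})
    return out


def to_undirected_simple(net: PhenotypeNetwork) -> nx.Graph:
    """Collapse parallel/directed records to single undirected edges.

    Self-loops are dropped.  Node attributes are carried over.
    """
    g = nx.Graph()
    for n, attrs in net.nodes.items():
        g.add_node(n, **attrs)
    for rec in net.edges:
        if rec.node_a != rec.node_b:
            g.add_edge(rec.node_a, rec.node_b)
    return g


def topology_summary(graph: nx.Graph) -> dict:
    """NetworkAnalyzer-style summary of an undirected simple graph."""
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    degrees = dict(graph.degree())
    return {
        "node_count": n,
        "edge_count": m,
        "density": nx.density(graph) if n > 1 else 0.0,
        "avg_degree": (2.0 * m / n) if n else 0.0,
        "mean_clustering": nx.average_clustering(graph) if n else 0.0,
        "component_count": nx.number_connected_components(graph) if n else 0,
        "degree_distribution": dict(Counter(degrees.values())),
    }


# ---------------------------------------------------------------------------
# deterministic worked example
# ---------------------------------------------------------------------------

def build_reference_census_network() -> tuple:
    """A deterministic network reproducing a published-scale component census.

    433 proteins / 1,790 interactions before curation, containing:
    a 424-node, 1,589-edge main block whose first 82 nodes are core; a hub of
    degree 175 attached to the main block and to a 4-node calcineurin-like
    cycle; two 2-node satellite components; and 20 redundant edges inside the
    main block that are curated away together with the hub.

    Returns (net, hub_id, extra_edges, small_component_node_sets).
    """
    net = PhenotypeNetwork()
    main = [f"P{i:03d}" for i in range(1, 425)]
    for i, n in enumerate(main):
        net.add_node(n, role="core" if i < 82 else "shell")

    def binding(a: str, b: str) -> InteractionRecord:
        return InteractionRecord(a, b, "binding", "none", 0.95, "experimental")

    # main block: 1,589 simple edges from fixed offset families
    edges = []
    for off, limit in ((1, 423), (2, 422), (3, 421), (5, 323)):
        for i in range(limit):
            edges.append((main[i], main[i + off]))
    assert len(edges) == 1589
    for a, b in edges:
        net.add_edge(binding(a, b))

    # satellite components: 2 + 2 + 4 nodes
    small = [{"CD47", "SIRPA"}, {"IL1A", "S100A13"},
             {"PPP3R1", "PPP3CA", "PPIA", "RCAN1"}]
    for n in ("CD47", "SIRPA", "IL1A", "S100A13",
              "PPP3R1", "PPP3CA", "PPIA", "RCAN1"):
        net.add_node(n, role="shell")
    net.add_edge(binding("CD47", "SIRPA"))
    net.add_edge(binding("IL1A", "S100A13"))
    cycle = ["PPP3R1", "PPP3CA", "PPIA", "RCAN1"]
    for a, b in zip(cycle, cycle[1:] + cycle[:1]):
        net.add_edge(binding(a, b))

    # hub: degree 175 (174 main-block partners + the calcineurin-like cycle)
    hub = "UBC"
    net.add_node(hub, role="shell")
    for n in main[:174]:
        net.add_edge(InteractionRecord(hub, n, "ptm:ubiquitination", "ab",
                                       0.95, "experimental"))
    net.add_edge(InteractionRecord(hub, "PPP3R1", "ptm:ubiquitination", "ab",
                                   0.95, "experimental"))

    # 20 redundant (curated) edges inside the main block
    extra_edges = [("P001", f"P{i:03d}") for i in range(200, 220)]
    for a, b in extra_edges:
        net.add_edge(binding(a, b))

    assert net.n_nodes == 433 and net.n_edges == 1790
    return net, hub, extra_edges, small
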