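"""Pathway-overlap (crosstalk) network from shared differentially expressed genes.

Every enriched pathway is first restricted to genes measurable on the study's
platforms (its "S-list").  Pairs of pathways with at least one process-tagged
member are connected when their S-lists share at least five upregulated or at
least five downregulated genes; the two directions are thresholded
independently, never summed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Set

from .enrichment import GeneSetCatalog


@dataclass(frozen=True)
class OverlapEdge:
    set_a: str
    set_b: str
    shared_up: frozenset
    shared_down: frozenset

    def __post_init__(self) -> None:
        if self.set_a >= self.set_b:
            raise ValueError("edge endpoints must be in canonical (a < b) order")

    @property
    def n_up(self) -> int:
        return len(self.shared_up)

    @property
    def n_down(self) -> int:
        return len(self.shared_down)


@dataclass
class OverlapNetwork:
    nodes: dict = field(default_factory=dict)  # term id -> {"tag", "size"}
    edges: list = field(default_factory=list)

    def neighbors(self, term: str) -> list:
        out = []
        for e in self.edges:
            if e.set_a == term:
                out.append((e.set_b, e))
            elif e.set_b == term:
                out.append((e.set_a, e))
        return out


def compute_s_list(term_genes: Iterable[str], platform_union: Iterable[str]) -> set:
    """Pathway genes measurable on the platforms."""
    return set(term_genes) & set(platform_union)


def shared_deg_counts(s_list_a: Set[str], s_list_b: Set[str],
                      up: Set[str], down: Set[str]) -> tuple:
    """Shared up/down DEGs in the intersection of two S-lists."""
    up, down = set(up), set(down)
    if up & down:
        raise ValueError("up and down gene lists overlap")
    common = set(s_list_a) & set(s_list_b)
    shared_up = common & up
    shared_down = common & down
    return len(shared_up), len(shared_down), shared_up, shared_down


def build_overlap_network(catalog: GeneSetCatalog, up: Set[str], down: Set[str],
                          platform_union: Set[str], min_shared: int = 5,
                          node_size: str = "pathway") -> OverlapNetwork:
    """Overlap network over a filtered (non-disease, PPI-bearing) catalog.

    Candidate pairs are all unordered pairs with at least one process-tagged
    member (process–process pairs qualify through either member).  An edge is
    retained when the pair shares >= min_shared up genes OR >= min_shared down
    genes.  node_size "pathway" uses the full pathway gene count; "s-list"
    uses the platform-restricted count.
    """
    terms = sorted(catalog.sets)
    if not any(catalog[t].functional_tag == "process" for t in terms):
        warnings.warn("no process-tagged terms; overlap network is empty")
    net = OverlapNetwork()
    s_lists = {t: compute_s_list(catalog[t].genes, platform_union) for t in terms}
    for t in terms:
        gs = catalog[t]
        size = len(gs.genes) if node_size == "pathway" else len(s_lists[t])
        net.nodes[t] = {"tag": gs.functional_tag, "size": size}
    for a, b in combinations(terms, 2):
        if "process" not in (catalog[a].functional_tag, catalog[b].functional_tag):
            continue
        n_up, n_down, shared_up, shared_down = shared_deg_counts(
            s_lists[a], s_lists[b], up, down)
        if n_up >= min_shared or n_down >= min_shared:
            net.edges.append(OverlapEdge(a, b, frozenset(shared_up),
                                         frozenset(shared_down)))
    return net


def partner_profile(term: str, network: OverlapNetwork) -> list:
    """Partners of one pathway, sorted by total shared DEGs (desc, ties by id).

    Each row is (partner id, n_up, n_down, partner functional tag); an
    isolated pathway yields an empty list.
    """
    if term not in network.nodes:
        raise KeyError(f"term {term!r} not in network")
    rows = [
        (partner, e.n_up, e.n_down, network.nodes[partner]["tag"])
        for partner, e in network.neighbors(term)
    ]
    rows.sort(key=lambda r: (-(r[1] + r[2]), r[0]))
    return rows
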