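"""End-to-end orchestration: simulate -> dge -> enrich -> overlap -> network -> mcode.

One YAML-loadable configuration drives all stages; every threshold defaults to
the analysis conventions used throughout the package (fold change 2, p 0.05,
EASE 0.05, fold enrichment 1.5, 5 shared DEGs, interaction score 0.9).  All
randomness flows from a single integer seed.  Each stage writes its
intermediate tables into the run directory and the run closes with a manifest
JSON recording every headline count.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import io as pio
from .dge import consensus_calls
from .enrichment import Background, enrich_gene_list, filter_pathways
from .mcode import MCODEParams, cluster_report, find_complexes, postprocess
from .network import (annotate, assemble_network, connected_components,
                      core_shell_split, filter_interactions, remove_node,
                      to_undirected_simple, topology_summary)
from .overlap import build_overlap_network
from .simulate import (StudyConfig, simulate_annotations, simulate_catalog,
                       simulate_expression_studies, simulate_interactome)

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "dge", "enrich", "overlap", "network", "mcode")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "phenonet_run"
    stages: Sequence[str] = ALL_STAGES
    # selection thresholds
    fc_cut: float = 2.0
    p_cut: float = 0.05
    ease_cut: float = 0.05
    fe_cut: float = 1.5
    min_shared: int = 5
    min_score: float = 0.9
    background_mode: str = "annotated"
    mcode: MCODEParams = field(default_factory=MCODEParams)
    # synthetic study conditions
    study: StudyConfig = field(default_factory=StudyConfig)
    n_sets: int = 20
    set_size_range: tuple = (40, 80)
    n_planted_sets: int = 3
    planted_hits: int = 25
    category_map: dict = field(default_factory=lambda: {
        "immune system": 5, "signal transduction": 5,
        "human diseases": 3, "metabolism": 2})
    n_shell: int = 150
    background_edge_prob: float = 0.02
    complexes: Sequence[tuple] = ((8, 1.0), (6, 0.9))
    hub_degree: int = 40
    dna_binding_fraction: float = 0.2
    n_go_terms: int = 5
    n_drugs: int = 3

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        self.study.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        study = StudyConfig(**raw.pop("study", {}))
        mcode = MCODEParams(**raw.pop("mcode", {}))
        if "complexes" in raw:
            raw["complexes"] = [tuple(c) for c in raw["complexes"]]
        if "set_size_range" in raw:
            raw["set_size_range"] = tuple(raw["set_size_range"])
        return cls(study=study, mcode=mcode, **raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["complexes"] = [list(c) for c in self.complexes]
        d["set_size_range"] = list(self.set_size_range)
        return d


def run_pipeline(config: PipelineConfig, outdir: Optional[str] = None) -> Path:
    """Execute the configured stages and return the run directory."""
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.echo(), "counts": {}}
    counts = manifest["counts"]
    stages = set(config.stages)

    pairs = truth = None
    if "simulate" in stages:
        pairs, truth = simulate_expression_studies(config.study)
        for rma, mas5 in pairs:
            pio.write_expression_tsv(rma, out / f"{rma.dataset_id}_rma.tsv")
            pio.write_expression_tsv(mas5, out / f"{mas5.dataset_id}_mas5.tsv")
            pio.write_detection_tsv(mas5.detection,
                                    out / f"{mas5.dataset_id}_detection.tsv")
        planted_ids = [f"PW{i:04d}" for i in range(1, config.n_planted_sets + 1)]
        universe = sorted(set().union(*(set(r.values.index) for r, _ in pairs)))
        # a planted set cannot hold more true genes than exist or than it has room for
        hits = min(config.planted_hits, len(truth.true_up),
                   config.set_size_range[0])
        catalog, cat_truth = simulate_catalog(
            universe, config.n_sets, config.set_size_range,
            n_categories_map=config.category_map,
            planted={p: hits for p in planted_ids},
            true_up=truth.true_up, seed=config.seed + 1001)
        truth.true_enriched_sets = cat_truth.true_enriched_sets
        pio.write_catalog(catalog, out / "catalog.gmt", out / "catalog_meta.tsv")
        pio.write_truth(truth, out / "truth.json")
    else:
        catalog = None

    up = down = calls = None
    if "dge" in stages:
        if pairs is None:
            raise FileNotFoundError("dge stage needs simulated inputs")
        calls = consensus_calls(pairs, fc_cut=config.fc_cut, p_cut=config.p_cut)
        calls.to_csv(out / "consensus_calls.tsv", sep="\t")
        up = set(calls.index[calls["final"] == "up"])
        down = set(calls.index[calls["final"] == "down"])
        counts["n_up"] = len(up)
        counts["n_down"] = len(down)
        log.info("consensus: %d up, %d down", len(up), len(down))

    enriched_up = enriched_down = None
    platform_union = None
    if "enrich" in stages:
        if up is None or catalog is None:
            raise FileNotFoundError("enrich stage needs dge output and a catalog")
        platform_union = frozenset().union(
            *(set(r.values.index) for r, _ in pairs))
        bg = Background(platform_union)
        enriched_up = enrich_gene_list(up, catalog, bg, config.ease_cut,
                                       config.fe_cut, config.background_mode)
        enriched_down = enrich_gene_list(down, catalog, bg, config.ease_cut,
                                         config.fe_cut, config.background_mode)
        pio.write_enrichment_report(enriched_up, out / "enrichment_up.tsv")
        pio.write_enrichment_report(enriched_down, out / "enrichment_down.tsv")
        counts["n_enriched_up"] = int(enriched_up["enriched"].sum())
        counts["n_enriched_down"] = int(enriched_down["enriched"].sum())

    overlap_net = None
    if "overlap" in stages:
        if enriched_up is None:
            raise FileNotFoundError("overlap stage needs enrichment output")
        kept_up = filter_pathways(enriched_up[enriched_up["enriched"]], catalog)
        kept_down = filter_pathways(enriched_down[enriched_down["enriched"]],
                                    catalog)
        kept_terms = sorted(set(kept_up["Term"]) | set(kept_down["Term"]))
        sub_catalog = type(catalog)()
        for t in kept_terms:
            sub_catalog.add(catalog[t])
        overlap_net = build_overlap_network(
            sub_catalog, up, down, platform_union, min_shared=config.min_shared)
        pio.write_overlap_network(overlap_net, out / "overlap.sif",
                                  out / "overlap_edges.tsv",
                                  out / "overlap_nodes.tsv")
        counts["n_overlap_terms"] = len(overlap_net.nodes)
        counts["n_overlap_edges"] = len(overlap_net.edges)

    net = None
    if "network" in stages:
        core = _select_core(overlap_net, catalog, truth)
        records, ppi_truth = simulate_interactome(
            core, config.n_shell, config.background_edge_prob,
            config.complexes, config.hub_degree, seed=config.seed + 2001)
        truth.true_complexes = ppi_truth.true_complexes
        truth.hub_id = ppi_truth.hub_id
        pio.write_interactions_tsv(records, out / "interactions.tsv")
        pio.write_truth(truth, out / "truth.json")

        qualifying = filter_interactions(records, min_score=config.min_score)
        net = assemble_network(core, qualifying)
        counts["network_nodes_before"] = net.n_nodes
        counts["network_edges_before"] = net.n_edges
        if truth.hub_id and truth.hub_id in net.nodes:
            net = remove_node(net, truth.hub_id)
        counts["network_nodes_after"] = net.n_nodes
        counts["network_edges_after"] = net.n_edges
        comps = connected_components(net)
        counts["component_sizes"] = [c.n_nodes for c in comps]
        net = comps[0]

        terms, dna, drugs = simulate_annotations(
            sorted(net.nodes), config.dna_binding_fraction, config.n_go_terms,
            config.n_drugs, seed=config.seed + 3001)
        net = annotate(net, calls, dna_binding=dna, drug_targets=drugs)
        core_net, shell_net = core_shell_split(net)
        counts["core_nodes"] = core_net.n_nodes
        counts["core_edges"] = core_net.n_edges
        counts["shell_edges"] = shell_net.n_edges
        pio.write_sif(net, out / "network.sif")
        pio.write_node_attributes(net, out / "network_nodes.tsv")
        pio.write_graphml(net, out / "network.graphml")
        simple = to_undirected_simple(net)
        manifest["topology"] = {
            k: v for k, v in topology_summary(simple).items()
            if k != "degree_distribution"
        }

    if "mcode" in stages:
        if net is None:
            raise FileNotFoundError("mcode stage needs the assembled network")
        simple = to_undirected_simple(net)
        clusters = postprocess(simple, find_complexes(simple, config.mcode),
                               config.mcode)
        report = cluster_report(simple, clusters, net)
        report.to_csv(out / "clusters.tsv", sep="\t", index=False)
        counts["n_clusters"] = len(clusters)

    pio.write_manifest(manifest, out / "manifest.json")
    return out


def _select_core(overlap_net, catalog, truth) -> set:
    """Pick the seed pathway: the process pathway with the most overlap partners.

    Mirrors the study design of choosing the process pathway connected to the
    largest number of other pathways; falls back to the first planted set when
    no overlap network is available.
    """
    if overlap_net is not None and overlap_net.edges:
        degree: dict = {}
        for e in overlap_net.edges:
            for t in (e.set_a, e.set_b):
                if overlap_net.nodes[t]["tag"] == "process":
                    degree[t] = degree.get(t, 0) + 1
        if degree:
            best = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            return set(catalog[best].genes)
    if truth is not None and truth.true_enriched_sets:
        return set(catalog[truth.true_enriched_sets[0]].genes)
    raise ValueError("no candidate core pathway available")
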