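"""Seeded synthetic inputs with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: several two-group expression studies measured on partially
overlapping platforms, each seen through two imperfectly agreeing
normalization views (a log2 quantile-aligned view and a linear view with
present/absent detection calls); gene-set catalogs with planted enriched
sets; and a scored interactome containing a high-degree hub and planted
dense complexes.  Everything flows from one integer seed, and equal seeds
give byte-identical artifacts.

Expression model: per-gene baselines are uniform on log2 [4, 12] (the usual
microarray dynamic range) and samples scatter normally around them; planted
genes are shifted by +/- effect_log2 in cases only, in every dataset where
the gene is measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .dge import ExpressionDataset
from .enrichment import GeneSet, GeneSetCatalog
from .network import InteractionRecord


@dataclass
class StudyConfig:
    n_genes: int = 2000
    n_datasets: int = 3
    samples_per_group: Optional[List[Tuple[int, int]]] = None  # (cases, controls)
    platform_coverage: float = 1.0
    de_fraction_up: float = 0.05
    de_fraction_down: float = 0.05
    effect_log2: float = 2.0
    base_sd_log2: float = 0.5
    norm_view_noise_sd: float = 0.3
    detect_midpoint: float = 0.15  # percentile where P(present) = 0.5
    detect_slope: float = 12.0
    effect_attenuation_sd: float = 0.0  # per-dataset heterogeneity, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_group is None:
            self.samples_per_group = [(5, 5)] * self.n_datasets
        if len(self.samples_per_group) != self.n_datasets:
            raise ValueError("samples_per_group must list one pair per dataset")
        if self.n_genes < 1 or self.n_datasets < 1:
            raise ValueError("n_genes and n_datasets must be positive")
        for cases, controls in self.samples_per_group:
            if cases < 2 or controls < 2:
                raise ValueError("each group needs >= 2 samples")
        if not 0.0 < self.platform_coverage <= 1.0:
            raise ValueError("platform_coverage must lie in (0, 1]")
        if self.de_fraction_up < 0 or self.de_fraction_down < 0 \
                or self.de_fraction_up + self.de_fraction_down >= 1.0:
            raise ValueError("DE fractions must be >= 0 and sum below 1")
        if self.effect_log2 <= 0 or self.base_sd_log2 <= 0:
            raise ValueError("effect_log2 and base_sd_log2 must be positive")
        if self.norm_view_noise_sd < 0:
            raise ValueError("norm_view_noise_sd must be non-negative")


@dataclass
class GroundTruth:
    true_up: Set[str] = field(default_factory=set)
    true_down: Set[str] = field(default_factory=set)
    true_enriched_sets: List[str] = field(default_factory=list)
    true_complexes: List[Set[str]] = field(default_factory=list)
    hub_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.true_up & self.true_down:
            raise ValueError("true_up and true_down overlap")
        for complex_nodes in self.true_complexes:
            if len(complex_nodes) < 4:
                raise ValueError("planted complexes need >= 4 nodes")


def gene_universe(n_genes: int) -> List[str]:
    return [f"G{i:05d}" for i in range(1, n_genes + 1)]


def _quantile_align(values: np.ndarray) -> np.ndarray:
    """Plain quantile normalization: each column takes the mean sorted profile."""
    order = np.argsort(values, axis=0)
    ranks = np.argsort(order, axis=0)
    mean_profile = np.sort(values, axis=0).mean(axis=1)
    return mean_profile[ranks]


def simulate_expression_studies(cfg: StudyConfig) -> Tuple[list, GroundTruth]:
    """Two-view expression datasets with planted up/down genes.

    Returns ([(rma_like, mas5_like), ...], GroundTruth).  Planted counts are
    floor(n_genes x fraction); every planted gene is shifted in every dataset
    that measures it, in a fixed direction.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = gene_universe(cfg.n_genes)
    n_up = int(np.floor(cfg.n_genes * cfg.de_fraction_up))
    n_down = int(np.floor(cfg.n_genes * cfg.de_fraction_down))
    planted = rng.choice(cfg.n_genes, size=n_up + n_down, replace=False)
    true_up = {genes[i] for i in planted[:n_up]}
    true_down = {genes[i] for i in planted[n_up:]}
    truth = GroundTruth(true_up=true_up, true_down=true_down)

    baselines = rng.uniform(4.0, 12.0, size=cfg.n_genes)
    shift = np.zeros(cfg.n_genes)
    shift[planted[:n_up]] = cfg.effect_log2
    shift[planted[n_up:]] = -cfg.effect_log2

    pairs = []
    for d, (n_cases, n_controls) in enumerate(cfg.samples_per_group):
        ds_id = f"DS{d + 1}"
        if cfg.platform_coverage < 1.0:
            mask = rng.random(cfg.n_genes) < cfg.platform_coverage
            if not mask.any():
                mask[0] = True
        else:
            mask = np.ones(cfg.n_genes, dtype=bool)
        measured = [g for g, m in zip(genes, mask) if m]
        n_meas = len(measured)
        n_samples = n_cases + n_controls
        samples = [f"{ds_id}_case{i + 1}" for i in range(n_cases)] + \
                  [f"{ds_id}_ctrl{i + 1}" for i in range(n_controls)]
        groups = pd.Series(["case"] * n_cases + ["control"] * n_controls,
                           index=samples)

        effect = shift[mask]
        if cfg.effect_attenuation_sd > 0:
            effect = effect * max(
                0.0, 1.0 - abs(rng.normal(0.0, cfg.effect_attenuation_sd)))
        log2 = baselines[mask, None] + rng.normal(
            0.0, cfg.base_sd_log2, size=(n_meas, n_samples))
        log2[:, :n_cases] += effect[:, None]

        rma_values = pd.DataFrame(_quantile_align(log2), index=measured,
                                  columns=samples)
        rma = ExpressionDataset(ds_id, "rma-like", rma_values, "log2", groups)

        noisy = log2 + rng.normal(0.0, cfg.norm_view_noise_sd,
                                  size=(n_meas, n_samples))
        linear = pd.DataFrame(np.exp2(noisy), index=measured, columns=samples)
        # detection: P with probability rising logistically in the gene's
        # within-sample expression percentile
        pct = linear.rank(axis=0, pct=True).to_numpy()
        p_present = 1.0 / (1.0 + np.exp(
            -cfg.detect_slope * (pct - cfg.detect_midpoint)))
        calls = np.where(rng.random(p_present.shape) < p_present, "P", "A")
        detection = pd.DataFrame(calls, index=measured, columns=samples)
        mas5 = ExpressionDataset(ds_id, "mas5-like", linear, "linear", groups,
                                 detection=detection)
        pairs.append((rma, mas5))
    return pairs, truth


def simulate_catalog(universe: Sequence[str], n_sets: int,
                     size_range: Tuple[int, int],
                     n_categories_map: Optional[Dict[str, int]] = None,
                     planted: Optional[Dict[str, int]] = None,
                     true_up: Optional[Set[str]] = None,
                     has_ppi_prob: float = 0.9,
                     seed: int = 0) -> Tuple[GeneSetCatalog, GroundTruth]:
    """Gene-set catalog with optional planted enriched sets.

    planted maps set ids (which must be among the generated PW#### ids) to the
    number of true_up genes loaded into them, making those sets recoverably
    over-represented in an upregulated gene list.  n_categories_map assigns
    KEGG-style categories ("immune system", "human diseases", ...) to the
    first sets in order.  Returns the catalog plus a GroundTruth fragment with
    true_enriched_sets filled.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    lo, hi = size_range
    if lo < 1 or hi > len(universe) or lo > hi:
        raise ValueError("size_range must lie within the gene universe")
    ids = [f"PW{i:04d}" for i in range(1, n_sets + 1)]
    planted = dict(planted or {})
    for set_id in planted:
        if set_id not in ids:
            raise ValueError(f"planted id {set_id!r} not among generated ids")
    categories: List[str] = []
    for cat, count in (n_categories_map or {}).items():
        categories.extend([cat] * count)
    # the map is a target composition; excess assignments are dropped
    categories = categories[:n_sets]
    categories.extend(["other"] * (n_sets - len(categories)))

    true_up = sorted(true_up or ())
    tags = ("process", "signaling", "other")
    catalog = GeneSetCatalog()
    for idx, (set_id, category) in enumerate(zip(ids, categories)):
        size = int(rng.integers(lo, hi + 1))
        n_load = planted.get(set_id, 0)
        if n_load > min(size, len(true_up)):
            raise ValueError(f"cannot load {n_load} true genes into {set_id}")
        loaded = list(rng.choice(true_up, size=n_load, replace=False)) \
            if n_load else []
        rest_pool = [g for g in universe if g not in set(loaded)]
        rest = rng.choice(len(rest_pool), size=size - n_load, replace=False)
        members = frozenset(loaded) | {rest_pool[i] for i in rest}
        # cycle functional tags so every catalog carries a predictable mix
        catalog.add(GeneSet(
            id=set_id, name=f"synthetic pathway {set_id}", genes=members,
            category=category, functional_tag=tags[idx % 3],
            has_ppi=bool(rng.random() < has_ppi_prob)))
    truth = GroundTruth(true_enriched_sets=sorted(planted))
    return catalog, truth


def simulate_interactome(core: Set[str], n_shell: int,
                         background_edge_prob: float = 0.02,
                         complexes: Sequence[Tuple[int, float]] = (),
                         hub_degree: int = 0,
                         score_params: Tuple[float, float] = (20.0, 1.0),
                         noise_score_params: Tuple[float, float] = (2.0, 5.0),
                         high_conf_frac: float = 0.5,
                         core_edge_prob: float = 0.15,
                         seed: int = 0) -> Tuple[list, GroundTruth]:
    """Scored, typed interaction records with planted structure.

    Background edges form an Erdos-Renyi graph among the shell nodes; a
    high_conf_frac share of them score high (Beta(20, 1), mass near 1, like
    well-validated interactions) and the rest score low (Beta(2, 5)), which
    makes a >= 0.9 confidence filter meaningful.  Every core node receives one
    guaranteed high-score attachment edge to a shell node, and each planted
    complex one attachment to a core node, so the assembled first shell is
    connected.  An optional hub node receives hub_degree high-score edges.
    Returns (records, GroundTruth fragment).
    """
    rng = np.random.default_rng(seed)
    core = sorted(core)
    shell = [f"S{i:04d}" for i in range(1, n_shell + 1)]
    all_nodes = core + shell
    if hub_degree > len(all_nodes):
        raise ValueError("hub_degree exceeds available partner count")
    for size, density in complexes:
        if density > 1.0 or density < 0.0:
            raise ValueError("complex density must lie in [0, 1]")
        if size > n_shell:
            raise ValueError("complex larger than the shell")

    kinds = ("binding", "activation", "inhibition", "ptm:phosphorylation")

    def make_record(a: str, b: str, score: float) -> InteractionRecord:
        kind = kinds[int(rng.integers(0, len(kinds)))]
        if kind == "binding":
            direction = "none"
        else:
            direction = "ab" if rng.random() < 0.5 else "ba"
        return InteractionRecord(a, b, kind, direction, float(score),
                                 "experimental")

    records: List[InteractionRecord] = []
    seen: Set[frozenset] = set()

    def add(a: str, b: str, true_edge: bool) -> None:
        key = frozenset((a, b))
        if a == b or key in seen:
            return
        seen.add(key)
        params = score_params if true_edge else noise_score_params
        score = min(1.0, float(rng.beta(*params)))
        rec = make_record(a, b, score)
        if not true_edge and rng.random() < 0.2:
            rec = InteractionRecord(rec.node_a, rec.node_b, rec.kind,
                                    rec.direction, rec.score, "other")
        records.append(rec)

    # planted complexes occupy disjoint shell prefixes
    truth_complexes: List[Set[str]] = []
    offset = 0
    for size, density in complexes:
        members = shell[offset:offset + size]
        if len(members) < size:
            raise ValueError("not enough shell nodes for planted complexes")
        offset += size
        for i in range(size):
            for j in range(i + 1, size):
                if rng.random() < density:
                    add(members[i], members[j], True)
        truth_complexes.append(set(members))

    # a pathway's members interact among themselves: high-score core-core edges
    for i in range(len(core)):
        for j in range(i + 1, len(core)):
            if rng.random() < core_edge_prob:
                add(core[i], core[j], True)

    # Erdos-Renyi background among shell nodes (mixed-confidence scores)
    for i in range(n_shell):
        for j in range(i + 1, n_shell):
            if rng.random() < background_edge_prob:
                add(shell[i], shell[j], rng.random() < high_conf_frac)

    # guaranteed attachments: every core node to a shell node; planted
    # complexes live in the first shell, so every member anchors to a core node
    for c in core:
        partner = shell[int(rng.integers(0, n_shell))] if shell else None
        if partner is not None:
            add(c, partner, True)
    if core:
        for members in truth_complexes:
            for m in sorted(members):
                anchor = core[int(rng.integers(0, len(core)))]
                add(m, anchor, True)

    hub_id = None
    if hub_degree > 0:
        hub_id = "HUB"
        partners = rng.choice(len(all_nodes), size=hub_degree, replace=False)
        for i in partners:
            add(hub_id, all_nodes[i], True)

    truth = GroundTruth(true_complexes=truth_complexes, hub_id=hub_id)
    return records, truth


def simulate_annotations(nodes: Sequence[str], dna_binding_fraction: float = 0.2,
                         n_terms: int = 5, n_drugs: int = 3,
                         term_size_range: Tuple[int, int] = (3, 10),
                         seed: int = 0) -> Tuple[GeneSetCatalog, Set[str], Dict[str, Set[str]]]:
    """GO-like term sets, a DNA-binding node set and a drug -> target table."""
    if not 0.0 <= dna_binding_fraction <= 1.0:
        raise ValueError("dna_binding_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = list(nodes)
    n_dna = int(round(dna_binding_fraction * len(nodes)))
    dna = {nodes[i] for i in rng.choice(len(nodes), size=n_dna, replace=False)} \
        if n_dna else set()
    lo, hi = term_size_range
    hi = min(hi, len(nodes))
    lo = min(lo, hi)
    terms = GeneSetCatalog()
    for t in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1)) if hi >= lo >= 1 else 0
        members = {nodes[i]
                   for i in rng.choice(len(nodes), size=size, replace=False)}
        if members:
            terms.add(GeneSet(id=f"GO{t:04d}", name=f"synthetic term {t}",
                              genes=frozenset(members), category="go"))
    drugs = {}
    for d in range(1, n_drugs + 1):
        size = int(rng.integers(1, max(2, len(nodes) // 10 + 1)))
        drugs[f"drug{d}"] = {
            nodes[i] for i in rng.choice(len(nodes), size=size, replace=False)}
    return terms, dna, drugs
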