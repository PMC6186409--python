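"""Gene-set over-representation with the EASE-modified one-tailed Fisher test.

The EASE score is the hypergeometric upper-tail probability recomputed after
removing one of the list hits from the term (P(X >= count - 1)), the
conservative convention of the EASE/DAVID tools.  Enrichment reports carry the
DAVID-style columns (Count, List Total, Pop Hits, Pop Total, Fold Enrichment,
PValue, Bonferroni, Benjamini, FDR) and a term is flagged as enriched when
EASE <= 0.05 and fold enrichment >= 1.5 (both thresholds inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

REPORT_COLUMNS = [
    "Term", "Count", "%", "List Total", "Pop Hits", "Pop Total",
    "Fold Enrichment", "PValue", "Bonferroni", "Benjamini", "FDR",
]

EXCLUDED_CATEGORIES = frozenset({"human diseases", "metabolism"})


@dataclass
class GeneSet:
    id: str
    name: str
    genes: frozenset
    category: str = "other"
    functional_tag: str = "other"  # "process" | "signaling" | "other"
    has_ppi: bool = True

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.id} is empty")


@dataclass
class GeneSetCatalog:
    sets: dict = field(default_factory=dict)  # id -> GeneSet

    def add(self, gs: GeneSet) -> None:
        if gs.id in self.sets:
            raise ValueError(f"duplicate set id {gs.id}")
        self.sets[gs.id] = gs

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def annotated_genes(self) -> frozenset:
        """Union of all member genes (the DAVID-style annotated background)."""
        out: set = set()
        for gs in self:
            out |= gs.genes
        return frozenset(out)


@dataclass(frozen=True)
class Background:
    """Gene universe: union of genes annotated on the study's platforms."""
    universe: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "universe", frozenset(self.universe))


def _validate_counts(count: int, list_total: int, pop_hits: int, pop_total: int) -> None:
    if not (0 <= count <= min(list_total, pop_hits)):
        raise ValueError("count must lie in [0, min(list_total, pop_hits)]")
    if pop_hits > pop_total or list_total > pop_total:
        raise ValueError("list_total and pop_hits cannot exceed pop_total")
    if pop_total <= 0:
        raise ValueError("pop_total must be positive")


def hypergeom_upper_tail(count: int, list_total: int, pop_hits: int,
                         pop_total: int) -> float:
    """P(X >= count) for X ~ Hypergeometric(pop_total, pop_hits, list_total).

    Exact tail summation: each term is
    C(pop_hits, k) C(pop_total - pop_hits, list_total - k) / C(pop_total, list_total).
    For ordinary population sizes the sum is done in exact integer arithmetic
    and rounded once at the end; very large populations fall back to
    log-space accumulation.
    """
    _validate_counts(count, list_total, pop_hits, pop_total)
    if count <= 0:
        return 1.0
    kmax = min(list_total, pop_hits)
    kmin = max(0, list_total - (pop_total - pop_hits))
    if count <= kmin:
        return 1.0
    if pop_total <= 50_000:
        numer = sum(
            math.comb(pop_hits, k) * math.comb(pop_total - pop_hits, list_total - k)
            for k in range(count, kmax + 1))
        tail = Fraction(numer, math.comb(pop_total, list_total))
        return float(min(tail, Fraction(1)))
    lg = math.lgamma

    def log_comb(n: int, k: int) -> float:
        return lg(n + 1) - lg(k + 1) - lg(n - k + 1)

    denom = log_comb(pop_total, list_total)
    terms = [
        log_comb(pop_hits, k) + log_comb(pop_total - pop_hits, list_total - k) - denom
        for k in range(count, kmax + 1)
    ]
    return float(min(1.0, math.exp(logsumexp(terms))))


def ease_score(count: int, list_total: int, pop_hits: int, pop_total: int) -> float:
    """EASE score: the upper tail with one list hit removed, P(X >= count - 1)."""
    _validate_counts(count, list_total, pop_hits, pop_total)
    return hypergeom_upper_tail(max(count - 1, 0), list_total, pop_hits, pop_total)


def fold_enrichment(count: int, list_total: int, pop_hits: int, pop_total: int) -> float:
    """(Count / List Total) / (Pop Hits / Pop Total)."""
    if list_total <= 0 or pop_hits <= 0:
        raise ValueError("list_total and pop_hits must be positive")
    return (count / list_total) / (pop_hits / pop_total)


def adjust_pvalues(ps: Sequence[float], method: str = "benjamini_hochberg") -> np.ndarray:
    """Bonferroni or Benjamini–Hochberg step-up adjustment, clamped at 1."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        return ps
    if method == "bonferroni":
        return multipletests(ps, method="bonferroni")[1]
    if method == "benjamini_hochberg":
        return multipletests(ps, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def enrich_gene_list(genes: Iterable[str], catalog: GeneSetCatalog, bg: Background,
                     ease_cut: float = 0.05, fe_cut: float = 1.5,
                     background_mode: str = "annotated") -> pd.DataFrame:
    """Over-representation of every catalog term in a gene list.

    background_mode "annotated" restricts the population (and the tested list)
    to background genes that appear in at least one catalog set, as DAVID
    does; "full-universe" uses the whole platform universe.  Terms with no
    list hits are omitted.  Rows are sorted by EASE score, ties by term id.
    """
    if background_mode == "annotated":
        population = frozenset(bg.universe & catalog.annotated_genes())
    elif background_mode == "full-universe":
        population = bg.universe
    else:
        raise ValueError(f"unknown background_mode {background_mode!r}")

    gene_list = set(genes) & population
    pop_total = len(population)
    list_total = len(gene_list)
    rows = []
    if list_total:
        for gs in catalog:
            term_genes = gs.genes & population
            count = len(gene_list & term_genes)
            if count == 0:
                continue
            pop_hits = len(term_genes)
            ease = ease_score(count, list_total, pop_hits, pop_total)
            fisher = hypergeom_upper_tail(count, list_total, pop_hits, pop_total)
            fe = fold_enrichment(count, list_total, pop_hits, pop_total)
            rows.append({
                "Term": gs.id,
                "Count": count,
                "%": 100.0 * count / list_total,
                "List Total": list_total,
                "Pop Hits": pop_hits,
                "Pop Total": pop_total,
                "Fold Enrichment": fe,
                "PValue": ease,
                "fisher_p": fisher,
                "category": gs.category,
                "functional_tag": gs.functional_tag,
                "has_ppi": gs.has_ppi,
                "enriched": ease <= ease_cut and fe >= fe_cut,
            })
    df = pd.DataFrame(rows, columns=[
        "Term", "Count", "%", "List Total", "Pop Hits", "Pop Total",
        "Fold Enrichment", "PValue", "fisher_p", "category", "functional_tag",
        "has_ppi", "enriched",
    ])
    if len(df):
        df["Bonferroni"] = adjust_pvalues(df["PValue"], "bonferroni")
        df["Benjamini"] = adjust_pvalues(df["PValue"], "benjamini_hochberg")
        df["FDR"] = 100.0 * df["Benjamini"]  # DAVID prints FDR as a percentage
        df = df.sort_values(["PValue", "Term"], kind="mergesort").reset_index(drop=True)
    else:
        df["Bonferroni"] = df["Benjamini"] = df["FDR"] = pd.Series(dtype=float)
    return df


def filter_pathways(rows: pd.DataFrame, catalog: GeneSetCatalog) -> pd.DataFrame:
    """Drop disease/metabolism terms and terms lacking protein interactions."""
    keep = []
    for term in rows["Term"]:
        if term not in catalog:
            raise KeyError(f"unknown term id {term!r}")
        gs = catalog[term]
        keep.append(gs.category not in EXCLUDED_CATEGORIES and gs.has_ppi)
    return rows[np.asarray(keep, dtype=bool)].reset_index(drop=True)
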