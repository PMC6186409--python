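"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV with a sample-id header and a group-label
row; gene sets as GMT (id TAB description TAB genes...); interactions as a
six-column TSV; networks as SIF plus attribute TSVs or GraphML.  All writers
round-trip through the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Optional

import networkx as nx
import pandas as pd

from .dge import ExpressionDataset
from .enrichment import GeneSet, GeneSetCatalog, REPORT_COLUMNS
from .network import InteractionRecord, PhenotypeNetwork
from .overlap import OverlapNetwork

GROUP_ROW = "__group__"


class FormatError(ValueError):
    """Malformed input line, reported with file and line number."""


# -- expression matrices -----------------------------------------------------

def write_expression_tsv(ds: ExpressionDataset, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene\t" + "\t".join(map(str, ds.values.columns)) + "\n")
        fh.write(GROUP_ROW + "\t" + "\t".join(ds.groups[c] for c in ds.values.columns) + "\n")
        for gene, row in ds.values.iterrows():
            fh.write(str(gene) + "\t" + "\t".join(repr(v) for v in row) + "\n")


def read_expression_tsv(path, dataset_id: str, view: str, scale: str,
                        detection: Optional[pd.DataFrame] = None) -> ExpressionDataset:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if GROUP_ROW not in raw.index:
        raise FormatError(f"{path}: missing {GROUP_ROW} row")
    groups = raw.loc[GROUP_ROW]
    values = raw.drop(index=GROUP_ROW).astype(float)
    return ExpressionDataset(dataset_id, view, values, scale,
                             pd.Series(groups), detection=detection)


def write_detection_tsv(detection: pd.DataFrame, path) -> None:
    detection.to_csv(path, sep="\t", index_label="gene")


def read_detection_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene", dtype=str)


# -- gene sets ---------------------------------------------------------------

def write_gmt(catalog: GeneSetCatalog, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for gs in sorted(catalog, key=lambda s: s.id):
            fh.write("\t".join([gs.id, gs.name, *sorted(gs.genes)]) + "\n")


def read_gmt(path) -> Dict[str, GeneSet]:
    """GMT records keyed by set id; every line needs >= 3 tab-separated fields."""
    path = Path(path)
    out: Dict[str, GeneSet] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            set_id, name, *genes = fields
            out[set_id] = GeneSet(id=set_id, name=name, genes=frozenset(genes))
    return out


def write_catalog(catalog: GeneSetCatalog, gmt_path, meta_path) -> None:
    """GMT plus a category metadata TSV (set id, category, tag, has_ppi)."""
    write_gmt(catalog, gmt_path)
    rows = [
        {"set_id": gs.id, "category": gs.category,
         "functional_tag": gs.functional_tag, "has_ppi": gs.has_ppi}
        for gs in sorted(catalog, key=lambda s: s.id)
    ]
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


def read_catalog(gmt_path, meta_path) -> GeneSetCatalog:
    sets = read_gmt(gmt_path)
    meta = pd.read_csv(meta_path, sep="\t", index_col="set_id")
    catalog = GeneSetCatalog()
    for set_id, gs in sets.items():
        if set_id in meta.index:
            row = meta.loc[set_id]
            gs = GeneSet(id=gs.id, name=gs.name, genes=gs.genes,
                         category=str(row["category"]),
                         functional_tag=str(row["functional_tag"]),
                         has_ppi=bool(row["has_ppi"]))
        catalog.add(gs)
    return catalog


# -- interactions and networks ----------------------------------------------

INTERACTION_COLUMNS = ["node_a", "node_b", "kind", "direction", "score", "evidence"]


def write_interactions_tsv(records: Iterable[InteractionRecord], path) -> None:
    rows = [
        {"node_a": r.node_a, "node_b": r.node_b, "kind": r.kind,
         "direction": r.direction, "score": repr(r.score), "evidence": r.evidence}
        for r in records
    ]
    pd.DataFrame(rows, columns=INTERACTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_interactions_tsv(path) -> list:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(INTERACTION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(InteractionRecord(
                row["node_a"], row["node_b"], row["kind"], row["direction"],
                float(row["score"]), row["evidence"]))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}:{i + 2}: {exc}") from exc
    return records


def write_sif(net: PhenotypeNetwork, path) -> None:
    """One `a <kind> b` line per record (one interaction-type token)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in net.edges:
            fh.write(f"{rec.node_a}\t{rec.kind}\t{rec.node_b}\n")
        linked = {n for e in net.edges for n in (e.node_a, e.node_b)}
        for node in sorted(set(net.nodes) - linked):
            fh.write(f"{node}\n")


def read_sif(path) -> list:
    """(node_a, kind, node_b) triples; isolated nodes come back as 1-tuples."""
    path = Path(path)
    out = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                out.append((fields[0],))
            elif len(fields) == 3:
                out.append(tuple(fields))
            else:
                raise FormatError(f"{path}:{lineno}: SIF line needs 1 or 3 fields")
    return out


def write_node_attributes(net: PhenotypeNetwork, path) -> None:
    rows = []
    for node in sorted(net.nodes):
        attrs = net.nodes[node]
        rows.append({
            "node": node, "role": attrs["role"],
            "regulation": attrs["regulation"],
            "magnitude": "" if attrs["magnitude"] is None else repr(attrs["magnitude"]),
            "dna_binding": attrs["dna_binding"],
            "drug_targets": ";".join(attrs["drug_targets"]),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_graphml(net: PhenotypeNetwork, path) -> None:
    g = nx.MultiGraph()
    for node, attrs in net.nodes.items():
        g.add_node(node, role=attrs["role"], regulation=attrs["regulation"],
                   magnitude=float("nan") if attrs["magnitude"] is None
                   else float(attrs["magnitude"]),
                   dna_binding=bool(attrs["dna_binding"]),
                   drug_targets=";".join(attrs["drug_targets"]))
    for rec in net.edges:
        g.add_edge(rec.node_a, rec.node_b, kind=rec.kind,
                   direction=rec.direction, score=rec.score,
                   evidence=rec.evidence)
    nx.write_graphml(g, path)


# -- overlap networks --------------------------------------------------------

def write_overlap_network(net: OverlapNetwork, sif_path, edge_attr_path,
                          node_attr_path) -> None:
    with Path(sif_path).open("w") as fh:
        for e in net.edges:
            fh.write(f"{e.set_a}\toverlap\t{e.set_b}\n")
        linked = {t for e in net.edges for t in (e.set_a, e.set_b)}
        for term in sorted(set(net.nodes) - linked):
            fh.write(f"{term}\n")
    pd.DataFrame([
        {"set_a": e.set_a, "set_b": e.set_b, "n_up": e.n_up, "n_down": e.n_down,
         "shared_up": ";".join(sorted(e.shared_up)),
         "shared_down": ";".join(sorted(e.shared_down))}
        for e in net.edges
    ]).to_csv(edge_attr_path, sep="\t", index=False)
    pd.DataFrame([
        {"term": t, "tag": a["tag"], "size": a["size"]}
        for t, a in sorted(net.nodes.items())
    ]).to_csv(node_attr_path, sep="\t", index=False)


# -- reports and manifests ---------------------------------------------------

def write_enrichment_report(rows: pd.DataFrame, path) -> None:
    """DAVID-style report with the canonical column set."""
    cols = [c for c in REPORT_COLUMNS if c in rows.columns]
    rows[cols].to_csv(path, sep="\t", index=False)


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def write_truth(truth, path) -> None:
    payload = {
        "true_up": sorted(truth.true_up),
        "true_down": sorted(truth.true_down),
        "true_enriched_sets": list(truth.true_enriched_sets),
        "true_complexes": [sorted(c) for c in truth.true_complexes],
        "hub_id": truth.hub_id,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
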