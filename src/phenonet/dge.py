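"""Differential expression with cross-algorithm, cross-dataset consensus.

Each expression study is analyzed through two normalization routes ("rma-like",
log2 scale, and "mas5-like", linear scale with P/A detection calls).  A gene is
differentially expressed within one route when its linear fold change reaches 2
(up) or 1/2 (down) with a Welch-test p <= 0.05.  The two routes are reconciled
per dataset into an evidence grade, and grades are combined across datasets by
a selection rule that demands replicated upward (or downward) evidence and the
complete absence of contradicting evidence in any dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Call = str  # one of "+", "0", "-"  ("filtered" allowed on the mas5 side)

UP, NONE, DOWN = "+", "0", "-"
FILTERED = "filtered"

GRADE_U2 = "U2"
GRADE_U1 = "U1"
GRADE_D2 = "D2"
GRADE_D1 = "D1"
GRADE_NONE = "none"
GRADE_CONFLICT = "conflict"
GRADE_UNMEASURED = "unmeasured"


@dataclass
class ExpressionDataset:
    """One dataset under one normalization route.

    values is a gene/probe x sample matrix; groups maps each sample column to
    "case" or "control".  The detection matrix (P/M/A flags) is present exactly
    for the linear "mas5-like" view.
    """

    dataset_id: str
    view: str  # "rma-like" | "mas5-like"
    values: pd.DataFrame
    scale: str  # "log2" | "linear"
    groups: pd.Series
    detection: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.view not in ("rma-like", "mas5-like"):
            raise ValueError(f"unknown view {self.view!r}")
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"unknown scale {self.scale!r}")
        counts = self.groups.value_counts()
        for grp in ("case", "control"):
            if counts.get(grp, 0) < 2:
                raise ValueError(f"need >=2 {grp} samples in {self.dataset_id}")
        if (self.view == "mas5-like") != (self.detection is not None):
            raise ValueError("detection matrix present iff view is mas5-like")
        if self.scale == "linear" and (self.values.values <= 0).any():
            raise ValueError("linear-scale values must be positive")

    @property
    def case_columns(self) -> list:
        return [s for s, g in self.groups.items() if g == "case"]

    @property
    def control_columns(self) -> list:
        return [s for s, g in self.groups.items() if g == "control"]


@dataclass(frozen=True)
class TestResult:
    t: float
    df: float
    p: float
    fc_linear: float = float("nan")


@dataclass(frozen=True)
class DatasetEvidence:
    """Reconciled two-route evidence for one gene in one dataset.

    The raw (rma, mas5) call pair is retained because the cross-dataset rule
    distinguishes the [+, 0] and [0, +] orientations, which the grade alone
    collapses.
    """

    dataset_id: str
    rma_call: Call = NONE
    mas5_call: Call = NONE
    measured: bool = True

    @property
    def grade(self) -> str:
        if not self.measured:
            return GRADE_UNMEASURED
        return dataset_consensus(self.rma_call, self.mas5_call)

    @property
    def pattern(self) -> Optional[tuple]:
        """(rma, effective mas5) call pair; None when unmeasured."""
        if not self.measured:
            return None
        mas5 = NONE if self.mas5_call == FILTERED else self.mas5_call
        return (self.rma_call, mas5)


@dataclass
class RegulationCall:
    gene: str
    final: str  # "up" | "down" | "none"
    evidence: dict = field(default_factory=dict)  # dataset_id -> DatasetEvidence
    magnitude: Optional[float] = None  # log2 fold change annotation


# ---------------------------------------------------------------------------
# per-route statistics
# ---------------------------------------------------------------------------

def welch_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Welch unequal-variance t test.

    t = (mean x - mean y) / sqrt(s2x/nx + s2y/ny) with Welch–Satterthwaite
    degrees of freedom.  Degenerate zero-variance inputs: equal means give
    t = 0, p = 1; unequal means give the smallest positive p with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs >=2 observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return TestResult(t=0.0, df=float(nx + ny - 2), p=1.0)
        warnings.warn("zero pooled standard error with unequal means")
        t = np.inf if mx > my else -np.inf
        return TestResult(t=float(t), df=float(nx + ny - 2),
                          p=float(np.nextafter(0.0, 1.0)))
    t = (mx - my) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(t=float(t), df=float(df), p=float(min(p, 1.0)))


def linear_fold_change(x: Sequence[float], y: Sequence[float], scale: str) -> float:
    """Case/control fold change on the linear scale."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if scale == "linear":
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("linear-scale values must be positive")
        return float(x.mean() / y.mean())
    if scale == "log2":
        return float(2.0 ** (x.mean() - y.mean()))
    raise ValueError(f"unknown scale {scale!r}")


def detection_filter(ds: ExpressionDataset) -> set:
    """Genes with at least one present ("P") call in both groups."""
    if ds.detection is None:
        raise ValueError("detection filter needs a mas5-like view with P/A calls")
    det = ds.detection
    present_case = (det[ds.case_columns] == "P").any(axis=1)
    present_ctrl = (det[ds.control_columns] == "P").any(axis=1)
    return set(det.index[present_case & present_ctrl])


def per_gene_call(fc: float, p: float, fc_cut: float = 2.0, p_cut: float = 0.05) -> Call:
    """Three-state call from fold change and p value (thresholds inclusive)."""
    if fc <= 0:
        raise ValueError("fold change must be positive")
    if p <= p_cut:
        if fc >= fc_cut:
            return UP
        if fc <= 1.0 / fc_cut:
            return DOWN
    return NONE


# ---------------------------------------------------------------------------
# consensus rules
# ---------------------------------------------------------------------------

def dataset_consensus(call_rma: Call, call_mas5: Call) -> str:
    """Reconcile the two normalization routes into one evidence grade.

    A gene removed by the present-call filter contributes "filtered", which is
    treated as "0": the filter gates only the mas5 route, the rma route still
    speaks.
    """
    if call_mas5 == FILTERED:
        call_mas5 = NONE
    pair = (call_rma, call_mas5)
    if pair == (UP, UP):
        return GRADE_U2
    if pair in ((UP, NONE), (NONE, UP)):
        return GRADE_U1
    if pair == (DOWN, DOWN):
        return GRADE_D2
    if pair in ((DOWN, NONE), (NONE, DOWN)):
        return GRADE_D1
    if pair == (NONE, NONE):
        return GRADE_NONE
    if pair in ((UP, DOWN), (DOWN, UP)):
        return GRADE_CONFLICT
    raise ValueError(f"unknown call pair {pair!r}")


_UP_BLOCKERS = {GRADE_D2, GRADE_D1, GRADE_CONFLICT}
_DOWN_BLOCKERS = {GRADE_U2, GRADE_U1, GRADE_CONFLICT}


def cross_dataset_consensus(evidence: Iterable[DatasetEvidence]) -> str:
    """Final up/down/none call for one gene across datasets.

    up requires either one dataset with [+, +], or one dataset with [+, 0] and
    a different dataset with [0, +]; in both cases no dataset may carry any
    downward (or conflicting) evidence.  down is the mirror rule.  Unmeasured
    datasets are skipped.
    """
    evidence = [e for e in evidence if e.measured]
    if not evidence:
        raise ValueError("gene unmeasured in every dataset")
    grades = [e.grade for e in evidence]
    patterns = [e.pattern for e in evidence]

    if not (_UP_BLOCKERS & set(grades)):
        if GRADE_U2 in grades:
            return "up"
        if (UP, NONE) in patterns and (NONE, UP) in patterns:
            return "up"
    if not (_DOWN_BLOCKERS & set(grades)):
        if GRADE_D2 in grades:
            return "down"
        if (DOWN, NONE) in patterns and (NONE, DOWN) in patterns:
            return "down"
    return "none"


def collapse_probes_to_gene(probe_calls: Mapping[str, Call],
                            probe_to_gene: Mapping[str, Optional[str]]) -> dict:
    """Collapse probe-level calls to gene level: any "+" and no "-" is "+"."""
    by_gene: dict = {}
    for probe, call in probe_calls.items():
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        if isinstance(gene, (set, frozenset, list, tuple)):
            raise ValueError(f"probe {probe!r} maps to multiple genes")
        by_gene.setdefault(gene, []).append(call)
    out = {}
    for gene, calls in by_gene.items():
        has_up = UP in calls
        has_down = DOWN in calls
        if has_up and not has_down:
            out[gene] = UP
        elif has_down and not has_up:
            out[gene] = DOWN
        else:
            out[gene] = NONE
    return out


def stringency_counts(evidence_table: Mapping[str, Sequence[DatasetEvidence]],
                      k: int) -> tuple:
    """(n_up, n_down) under the "selected in at least k datasets" variant.

    A gene qualifies as up at level k when no dataset blocks it and either
    at least k datasets show [+, +], or both [+, 0] and [0, +] orientations
    occur and at least k datasets carry upward evidence.  k = 1 reduces to the
    base cross-dataset rule; counts are non-increasing in k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_up = n_down = 0
    for evidence in evidence_table.values():
        evidence = [e for e in evidence if e.measured]
        if not evidence:
            continue
        if k > len(evidence):
            continue
        grades = [e.grade for e in evidence]
        patterns = [e.pattern for e in evidence]
        if not (_UP_BLOCKERS & set(grades)):
            n_u2 = grades.count(GRADE_U2)
            n_upward = n_u2 + grades.count(GRADE_U1)
            combo = (UP, NONE) in patterns and (NONE, UP) in patterns
            if n_u2 >= k or (combo and n_upward >= k):
                n_up += 1
                continue
        if not (_DOWN_BLOCKERS & set(grades)):
            n_d2 = grades.count(GRADE_D2)
            n_downward = n_d2 + grades.count(GRADE_D1)
            combo = (DOWN, NONE) in patterns and (NONE, DOWN) in patterns
            if n_d2 >= k or (combo and n_downward >= k):
                n_down += 1
    return n_up, n_down


# ---------------------------------------------------------------------------
# dataset-level drivers
# ---------------------------------------------------------------------------

def differential_table(ds: ExpressionDataset) -> pd.DataFrame:
    """Per-gene Welch test and fold change for one dataset view (vectorized)."""
    case = ds.values[ds.case_columns].to_numpy(dtype=float)
    ctrl = ds.values[ds.control_columns].to_numpy(dtype=float)
    nx, ny = case.shape[1], ctrl.shape[1]
    mx, my = case.mean(axis=1), ctrl.mean(axis=1)
    vx = case.var(axis=1, ddof=1)
    vy = ctrl.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate rows: both variances zero
    degenerate = se2 == 0.0
    equal = degenerate & (mx == my)
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    p = np.where(degenerate & ~equal, np.nextafter(0.0, 1.0), p)
    df = np.where(degenerate, nx + ny - 2, df)
    if ds.scale == "linear":
        fc = mx / my
    else:
        fc = 2.0 ** (mx - my)
    return pd.DataFrame(
        {"t": t, "df": df, "p": np.minimum(p, 1.0), "fc": fc}, index=ds.values.index
    )


def call_dataset_pair(rma: ExpressionDataset, mas5: ExpressionDataset,
                      fc_cut: float = 2.0, p_cut: float = 0.05) -> pd.DataFrame:
    """Three-state calls for both routes of one dataset.

    Returns a frame indexed by gene with columns rma_call / mas5_call and the
    rma-route log2 fold change (used later as the magnitude annotation).
    Genes failing the present-call filter on the mas5 side get "filtered".
    """
    if rma.dataset_id != mas5.dataset_id:
        raise ValueError("views belong to different datasets")
    tab_r = differential_table(rma)
    tab_m = differential_table(mas5)
    retained = detection_filter(mas5)

    def _call(row) -> Call:
        return per_gene_call(row["fc"], row["p"], fc_cut, p_cut)

    calls_r = tab_r.apply(_call, axis=1)
    calls_m = tab_m.apply(_call, axis=1)
    calls_m[~calls_m.index.isin(retained)] = FILTERED

    genes = tab_r.index.union(tab_m.index)
    out = pd.DataFrame(index=genes)
    out["rma_call"] = calls_r.reindex(genes, fill_value=NONE)
    out["mas5_call"] = calls_m.reindex(genes, fill_value=NONE)
    out["log2_fc_rma"] = np.log2(tab_r["fc"]).reindex(genes)
    return out


def consensus_calls(study_pairs: Sequence[tuple],
                    fc_cut: float = 2.0, p_cut: float = 0.05) -> pd.DataFrame:
    """Full cross-dataset consensus over (rma-like, mas5-like) dataset pairs.

    Returns a frame indexed by gene with the final call, one grade column per
    dataset, and the magnitude (median across datasets of the rma-route log2
    fold change where the gene is measured).
    """
    per_dataset = {}
    for rma, mas5 in study_pairs:
        per_dataset[rma.dataset_id] = call_dataset_pair(rma, mas5, fc_cut, p_cut)
    all_genes = sorted(set().union(*(t.index for t in per_dataset.values())))

    records = []
    for gene in all_genes:
        evidence = []
        magnitudes = []
        row: dict = {"gene": gene}
        for ds_id, tab in per_dataset.items():
            if gene in tab.index:
                ev = DatasetEvidence(ds_id, tab.at[gene, "rma_call"],
                                     tab.at[gene, "mas5_call"])
                mag = tab.at[gene, "log2_fc_rma"]
                if np.isfinite(mag):
                    magnitudes.append(mag)
            else:
                ev = DatasetEvidence(ds_id, measured=False)
            evidence.append(ev)
            row[f"grade_{ds_id}"] = ev.grade
        row["final"] = cross_dataset_consensus(evidence)
        row["magnitude"] = float(np.median(magnitudes)) if magnitudes else np.nan
        records.append(row)
    out = pd.DataFrame.from_records(records).set_index("gene")
    return out


def evidence_table(study_pairs: Sequence[tuple],
                   fc_cut: float = 2.0, p_cut: float = 0.05) -> dict:
    """gene -> list of DatasetEvidence across datasets (for stringency scans)."""
    per_dataset = {}
    for rma, mas5 in study_pairs:
        per_dataset[rma.dataset_id] = call_dataset_pair(rma, mas5, fc_cut, p_cut)
    all_genes = sorted(set().union(*(t.index for t in per_dataset.values())))
    table = {}
    for gene in all_genes:
        evs = []
        for ds_id, tab in per_dataset.items():
            if gene in tab.index:
                evs.append(DatasetEvidence(ds_id, tab.at[gene, "rma_call"],
                                           tab.at[gene, "mas5_call"]))
            else:
                evs.append(DatasetEvidence(ds_id, measured=False))
        table[gene] = evs
    return table
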