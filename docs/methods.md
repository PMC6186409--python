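# Methods

This note documents the statistical models, the rules implemented, the
synthetic-data generator, and the numerical and design choices behind
`phenonet`.

## Consensus differential expression

**Per-route test.** Differential expression within one dataset view uses the
Welch unequal-variance t statistic, t = (x̄ − ȳ)/√(s²ₓ/nₓ + s²ᵧ/nᵧ), with
Welch–Satterthwaite degrees of freedom and a two-sided p value. Analyses of
this style rarely state sidedness; two-sided is the standard reading, with
the fold-change sign carrying direction. Fold change
is always reported on the linear scale: mean ratio for linear data,
2^(Δ mean) for log2 data, oriented case/control. Thresholds (FC ≥ 2 or
≤ 1/2, p ≤ 0.05) are inclusive. Degenerate zero-variance rows: equal means
give t = 0, p = 1; unequal means give the smallest positive double with a
warning.

**Detection filter.** The linear view carries P/A detection calls; a gene
survives only with at least one P among cases *and* at least one P among
controls. A filtered gene contributes call "0" (not "unmeasured") for that
dataset's linear route: the filter is a precondition of that route only, and
the log2 route still speaks.

**Within-dataset grades.** (+,+) → U2, (+,0)/(0,+) → U1, mirrored for down,
(0,0) → none, (+,−)/(−,+) → conflict. A conflict blocks both final
directions — the conservative resolution of a case the selection rules never
address.

**Cross-dataset rule.** Up requires ([+,+] somewhere) or ([+,0] in one
dataset and [0,+] in a *different* dataset), with no dataset showing any
downward or conflicting evidence; down is the mirror. Note the literal
asymmetry: two datasets both showing [+,0] do **not** make a final up call —
the rule demands both orientations. The evidence object therefore keeps the
raw call pair rather than only the collapsed grade. Unmeasured datasets
(platform coverage) are skipped.

**Stringency scan.** The "selected in at least k datasets" variant is not
formally defined beyond k = 1 in the source analysis; the implementation
counts a gene at level k when no dataset blocks it and either #[+,+] ≥ k, or
both U1 orientations occur and the total number of upward datasets is ≥ k.
This reduces exactly to the base rule at k = 1 and is monotone
non-increasing in k.

**Probe collapse.** Probe-level calls collapse to gene level by
any-up-and-none-down (mirrored), conflicts cancelling to "0"; probes mapped
to multiple genes are rejected. A best-probe alternative was considered and
not implemented: the selection rules are phrased at gene level and the
any/none rule mirrors them most directly.

**Magnitude annotation.** Where a single log2 fold change is attached to a
network node, it is the median across datasets of the log2 view's fold
change — a robust choice where no single canonical aggregation exists.

## Enrichment

The exact hypergeometric upper tail P(X ≥ k) for X ~ HG(N, K, n) is summed
in exact big-integer arithmetic (one rational, rounded once) for populations
up to 50,000 genes, falling back to log-space lgamma accumulation beyond
that. The EASE score is the same tail at k − 1 (one list hit removed), hence
EASE ≥ Fisher everywhere with equality only at k = 0. Fold enrichment is
(k/n)/(K/N).

Two background conventions are provided: "annotated" (population = platform
universe ∩ union of catalog genes, the DAVID convention; the tested list is
restricted the same way) and "full-universe". Selection uses the raw EASE
score; Bonferroni and Benjamini–Hochberg columns are reported for
completeness, with the DAVID-style "FDR" column given as BH × 100 (that tool
prints FDR as a percentage). Terms with zero list hits are omitted. Category
filtering drops "human diseases" and "metabolism" terms and terms lacking
protein interactions.

## Pathway overlap

S-list = pathway genes ∩ platform union. Candidate pairs are unordered pairs
with at least one process-tagged member (process–process pairs qualify);
an edge is kept when the pair shares ≥ 5 up **or** ≥ 5 down genes — the two
directions are never summed. Node size defaults to the full pathway gene
count (a switch selects S-list size instead, since either convention is
defensible for node sizing). No statistical test is attached to overlap counts; the raw
threshold is the method.

## Network assembly and analysis

Interaction records are typed (binding undirected; activation, inhibition
and `ptm:*` directed) and scored in [0, 1]. The confidence filter keeps
records with matching evidence ("experimental") and score ≥ 0.9, inclusive.
Assembly takes the core set plus every node sharing a qualifying record with
a core node; shell–shell records are retained only between already-qualified
nodes, and edgeless core proteins remain as isolates. The network is a
multigraph: a pair may carry a binding and a directed record simultaneously;
collapse to a simple undirected graph happens only in the projection used
for topology statistics and clustering (self-loops dropped).

Hub removal deletes a node with its incident records plus an explicit list
of curated extra edges — reproducing analyses where redundant partner edges
(e.g. ubiquitin-ligase duplicates) are removed by hand along with a hub; the
curated list is an input, not an inference. Components are ordered by node
count, then edge count, then smallest node id (tie-breaks are this package's
choice). The core/shell split partitions the edge multiset exactly:
core-induced edges vs the rest. Subnetwork induction keeps isolated members,
matching figure conventions where such proteins connect through the parent
network.

`build_reference_census_network` is a deterministic worked example at
published scale: 433 nodes / 1,790 edges, a degree-175 hub plus 20 curated
edges whose removal leaves 432 / 1,595, and satellite components of 2 + 2 +
4 nodes whose removal leaves a 424-node / 1,589-edge main component with 82
core proteins. Only these census totals are designed in; the internal wiring
(fixed offset families) is arbitrary.

## MCODE

Vertex weight w(v) = k_max × density of the highest k-core of the closed
neighborhood N[v] (loops excluded; isolated vertices weigh 0), so
0 ≤ w(v) ≤ deg(v). Seeds are visited in decreasing weight (ties by id);
breadth-first expansion admits unvisited neighbors with w ≥ w(seed) × (1 −
node_score_cutoff) up to max_depth; members are marked visited, making
clusters node-disjoint. Clusters lacking a k_core_filter-core are discarded.
Post-processing applies fluff (off by default; adds neighbors with closed-
neighborhood density > fluff_density, which may create overlaps) before
haircut (iterated removal of members with intra-cluster degree < 2), then
recomputes scores as density × size. All defaults (2 / 0.2 / 2 / haircut on /
fluff off / depth 100) follow the v1.5.1 plugin documentation; every run
logs its parameters. Cluster counts on real networks depend strongly on
these parameters and are not a reproduction target.

## Synthetic data

The generator emulates what the analysis assumes, not microarray physics:

- log2 expression ~ Normal(baselineᵍ, σ) with baselines ~ Uniform(4, 12)
  (typical microarray dynamic range); default σ = 0.5 log2 units.
- Planted genes (floor(n × fraction) of the universe, disjoint up/down sets)
  shift by ±effect_log2 (default 2, i.e. 4-fold) in cases, in every dataset
  measuring them, never reversed. A per-dataset attenuation knob exists for
  disease-heterogeneity experiments and defaults off.
- The log2 view is quantile-aligned across samples; the linear view is
  2^(log2 + Normal(0, 0.3)), so the two routes agree imperfectly and
  genuinely exercise the consensus rules. Detection is P with probability
  logistic in the within-sample expression percentile (midpoint 0.15, slope
  12): low-expressed transcripts are often absent, as real detection calls
  behave.
- Platform coverage masks each gene per dataset independently.
- Catalogs draw sets uniformly from the universe (sizes uniform in a range);
  planted sets are loaded with a stated number of truly-up genes; categories
  follow a requested composition and functional tags cycle
  process/signaling/other so every catalog has a predictable mix.
- Interactomes: Erdős–Rényi background among shell nodes with a
  high-confidence fraction (default 0.5) scoring Beta(20, 1) (mass near 1)
  and the rest Beta(2, 5), making the ≥ 0.9 filter meaningful; planted
  complexes are dense high-score subgraphs anchored into the first shell;
  core–core edges appear with probability 0.15 (a pathway's members interact
  among themselves, giving the connected core block the analysis expects);
  each core node receives one guaranteed shell attachment; an optional hub
  receives a requested degree. About 20% of noise edges carry non-
  experimental evidence tags.

Everything derives from one `numpy` Generator seed; equal seeds give
byte-identical artifacts.

**What passing tests do and do not show.** The generator has no batch
effects, probe-level artifacts, correlated genes, or inter-dataset
heterogeneity by default; planted effects are large (4-fold) relative to
noise. Recovery results (sensitivity ≥ 0.9 at 5 vs 5 samples, clean planted-
set enrichment, 8-clique MCODE recovery) therefore validate the *rules and
algorithms*, not the expected power on real tissue data, where effect sizes,
correlation structure and platform disagreement are all less favorable.

## Problem sizes and determinism

The shipped tests and the acceptance script use 2,000-gene studies with
three 5 vs 5 datasets, 20-set catalogs, and 150-node interactomes with one
planted 8-clique over p = 0.02 background — sizes chosen so the full suite
and script each run in seconds while leaving planted structure clearly
separated from noise. The rule-interpreter check enumerates all call-pair
combinations for up to three datasets exhaustively; the tail oracle checks
1,000 random configurations against exact rational arithmetic at < 1e−12.
Property tests use derandomized hypothesis profiles or fixed numpy seeds
throughout.
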