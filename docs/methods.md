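# Methods

This note documents the models implemented in `cdome`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic-data
generators do and do not emulate.

## The ternary expression matrix

The central object is a cells × CD-molecules grid with three call states:
POSITIVE, NEGATIVE and UNKNOWN. UNKNOWN encodes *never examined* and is
deliberately distinct from NEGATIVE — the size of the unexamined region is
itself a primary result of knowledge-gap mapping, so no operation silently
conflates the two. Collapsing to binary requires an explicit policy:

- `as_negative` (default for clustering and networks): UNKNOWN → 0. This
  treats absence of evidence as absence, which biases profiles of poorly
  studied cells toward the origin; it is the conservative convention when
  most analyses downstream count shared *positive* calls.
- `drop_marker` / `drop_cell`: restrict to fully observed columns/rows.
  Unbiased but can discard most of a sparse matrix.

How unexamined pairs should enter a clustering is genuinely undecidable
from first principles; the policy is therefore a named parameter rather
than a baked-in choice, and results should be read as conditional on it.

Alias resolution in the cell and molecule registries is case-insensitive
exact matching only — no fuzzy matching — so query expansion and lookups
are deterministic.

## Literature triage

Abstract screening uses two-class multinomial naive Bayes with additive
(Laplace) smoothing, the standard bag-of-words model for short biomedical
text. Priors come from class frequencies; token probabilities are
`(c_t + α) / (T_c + αV)` over the union vocabulary, α = 1 by default.
Scoring is done in log space. Two conventions matter:

- **Out-of-vocabulary tokens carry no evidence.** A record with no known
  tokens is decided by the priors alone. (The alternative — assigning OOV
  tokens a smoothed probability — shifts scores by class-dependent
  constants without any supporting count.)
- **Ties go to POSITIVE.** Predicted positives proceed to manual review,
  so a false positive costs reviewer time while a false negative silently
  loses a data point; recall is the binding constraint.

Tokenization is lowercased maximal alphanumeric runs (`CD8+ T cells` →
`cd8, t, cells`); it is idempotent on its own output. Evaluation reports
accuracy, sensitivity TP/(TP+FN) and specificity TN/(TN+FP) on a held-out
labeled set; the training protocol draws 200 positive and 200 negative
abstracts at random.

Coverage mapping is exact integer arithmetic: the fraction of
(cell, marker) pairs with at least *threshold* literature hits, reported
as numerator/denominator. Heat-map availability bands are 0 (none), 1–9
(low), 10–100 (mid, with a light→dark shade within the band), 101–999
(high), ≥1000 (top); the 1–9 and 101–999 assignments interpolate between
the bands the rendering convention defines explicitly, and are documented
as an interpretation.

## Half-life comparison

The question is whether a designated subset of genes (the CD surface
markers) turns over faster or slower than the proteome/transcriptome at
large. The test is a Monte Carlo resampling null: draw R random subsets of
the same size from the table **without replacement** (a random subset of
the dataset; a with-replacement bootstrap is available as an option),
compute the same per-channel statistic, and report the add-one empirical
p-value `(r + 1) / (R + 1)`, where `r` counts null draws at least as
extreme as the observed value in the stated tail. The add-one convention
keeps p in (0, 1] and is exact under the null. Two-sided p doubles the
smaller tail, capped at 1. The default statistic is the arithmetic mean
per channel (matching how such datasets are usually summarized); the
geometric mean is offered because half-lives are strongly right-skewed.
Default R = 10,000 with subset size 30.

Null draws are generated by ranking one uniform random key per gene and
taking the smallest `sample_size` — a vectorized, order-documented way to
draw uniform subsets that is bit-reproducible given the seed.

## Enrichment

One-sided (upper-tail) hypergeometric enrichment of a query gene set
against a background: `p = Σ_{i=b}^{min(B,n)} C(B,i)·C(N−B,n−i)/C(N,n)`,
accumulated in log space via `gammaln` and `logsumexp` so small p-values
are stable. Depletion is not tested. Query genes outside the background
are dropped with a warning (partial gene-name mapping is the norm for CD
designations — only a subset of CD entries has an assigned gene name);
an empty effective query is an error listing the dropped genes.

Benjamini–Hochberg step-up runs over the terms actually tested (those with
background term size ≥ `min_term_size`), not over all known terms:
`q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1, stable under ties.

Annotations are flat term → gene-set maps. No ontology-graph propagation
(parent-term inheritance) is performed; this diverges from full GO tooling
and means term p-values are independent of any term hierarchy.

## Clustering and networks

Distances between binary expression profiles are Euclidean (the customary
default of hierarchical-clustering pipelines, kept as the package default)
or Jaccard (the principled choice for presence/absence data; two all-zero
profiles are defined to be at distance 0, not NaN). Agglomeration supports
complete (default), average (UPGMA) and single linkage via the
Lance–Williams recurrences. Ties — common with integer-valued binary
distances — break deterministically by the smallest (node id, node id)
pair, so merge sequences are identical across platforms; heights are
non-decreasing for all three (monotone) linkages. `cut_k` undoes the last
k − 1 merges and numbers clusters by first-leaf appearance. The default
cut is k = 7, a parameter rather than a criterion: the package makes no
claim about how many clusters a given dataset "has".

Newick export writes an ultrametric tree in which a node merged at height
h sits at depth h/2, so cophenetic distances equal merge heights; labels
with spaces are single-quoted.

The commonality graph has one node per cell and an undirected edge
wherever at least `min_shared` markers are POSITIVE on both endpoints,
weighted by that count (equivalently, the off-diagonal of `G·Gᵀ`), with
the shared marker list stored on the edge and optional cluster labels on
nodes. Graphs are serialized as Graph Modelling Language (GML), the
plain-text format Cytoscape imports; reading and writing go through
networkx, and round-trips preserve nodes, edges and weights exactly.

## Synthetic data: what it emulates, and what it does not

Every pipeline input can be generated with retained ground truth, under a
single integer seed per spec with all draws taken from one generator in
documented order (bit-identical reruns).

**Corpus.** Abstracts are bag-of-words draws from class-conditional
multinomials over a synthetic vocabulary; the positive class up-weights a
designated signal-word block by an odds multiplier (default 8) and
renormalizes, with Poisson document lengths (mean 120, floored at 1).
This is exactly the family the classifier assumes, which makes recovery
analytically predictable: at multiplier 1 the classes are identical and
held-out accuracy is binomially distributed around 0.5; at multiplier 8
with ~120 tokens the Bayes error is negligible. Real abstracts violate
conditional independence (phrases, topical correlation), so the near-1.0
accuracies here bound what the *procedure* can do when its model is true;
they do not predict performance on genuine literature, where mid-0.7s
accuracy is a realistic outcome. Defaults: 400+400 records, so the
200+200 training protocol leaves a held-out 400.

**Expression matrix.** Each of `n_groups` lineage groups (default 7;
per-group sizes may be given, e.g. (6,6,5,5,5,5,5) for a 37-cell study)
owns a private core of `round(core_frac·n_markers)` markers (default 26 of
261) POSITIVE on all its cells; all other pre-noise calls are NEGATIVE.
Calls are then flipped with probability `flip_noise` (default 0.05) and
masked UNKNOWN with probability `missing_rate` (default 0.2 — moderate
incompleteness that leaves the planted structure recoverable; the far
higher missingness of real literature-curated matrices is the subject of
the coverage analysis, which uses the missingness mask directly). The
pre-noise grid and group labels are retained so recovery tests compare
against truth rather than re-deriving it. Real marker sharing between
lineages (e.g. pan-leukocyte antigens) is *not* emulated: between-group
profiles are maximally separated, so clustering recovery here demonstrates
correctness of the algorithm, not expected performance on real data.

**Hit counts.** Examined (non-UNKNOWN) pairs receive ≥1 hit with
geometric extra counts (heavy right tail, echoing the concentration of
literature on a few well-studied pairs); unexamined pairs receive 0. The
simulated coverage fraction therefore tracks `1 − missing_rate`.

**Half-lives.** Log-normal per channel; the mean parameters are geometric
means (exp of the log-mean), with `log_sd` = 0.8 (about a 2.2× geometric
SD, the order of spread seen in genome-wide turnover data). Defaults plant
a 30-gene subset at 18 h mRNA / 16 h protein against a 9 h / 46 h global
background in a 5000-gene table — a fast-protein-turnover regime in which
the lower-tail Monte Carlo p for protein is expected below 0.01
essentially always at R = 1000. Arithmetic means of log-normal samples
exceed the geometric-mean parameters by `exp(log_sd²/2)` (~1.38); tests
and reports that quote "means" use the statistic they name.

**Annotations.** Background terms annotate uniform random gene subsets
(sizes uniform on 5–50); one planted term covers a designated gene set
plus optional noise padding. With a 20/20 planted overlap in a 1000-gene
background the planted term's p (~10⁻³⁰) dominates any noise term, so
rank-1 recovery is the expected outcome and failures indicate defects,
not noise.

## Orchestration and determinism

`run_pipeline` derives one sub-seed per randomness consumer from the root
seed via `numpy.random.SeedSequence` (all below 2³¹), executes stages in
dependency order, and writes a manifest with SHA-256 checksums of every
artifact. JSON is written with sorted keys and floats via `repr`, TSVs
with fixed newline conventions, so a fixed seed yields byte-identical
manifests across runs — verified in the test suite. Problem sizes in the
default demo (37 cells × 261 markers, 800 abstracts, 5000 genes, 10,000
resamples) run end-to-end in seconds on one core.

## Known limitations

- No live PubMed client: hit counts enter as files; the query builder
  exists so real counts can be plugged in.
- No ontology-aware enrichment (flat annotation sets only).
- No quantitative (fraction-positive) modelling: the optional fraction on
  a call is stored and validated but not used by any analysis.
- The naive Bayes generator/classifier pair shares one model family, so
  triage results on synthetic corpora are upper bounds by construction.
- Cluster count k and the UNKNOWN policy are parameters with documented
  defaults, not inferred quantities.
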