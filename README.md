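# cdome

Analysis toolkit for characterizing the **CDome** — the complement of CD
(cluster of differentiation) surface molecules expressed on hematopoietic
cells — from literature-derived expression calls.

Systematic knowledge of which CD markers sit on which blood-lineage cells
underpins immunophenotyping panels and antibody therapeutics, yet the
primary literature covers only a small fraction of all (cell, marker)
combinations. This package implements the full desk workflow for mapping
and analysing that knowledge landscape, for computational immunologists and
systems biologists:

1. **Literature triage** — build `"<cell> AND <marker>"` query lists with
   alias expansion, and screen abstracts with a multinomial naive Bayes
   classifier (Laplace smoothing, tie-break toward the positive class so no
   data point is lost before manual review).
2. **Knowledge-gap mapping** — per-pair hit-count matrices, the exact
   coverage fraction `#{pairs with ≥1 hit} / #pairs`, per-cell
   characterization rankings, and the availability bands used for heat-map
   rendering (0 / 1–9 / 10–100 / 101–999 / 1000+ hits).
3. **The ternary expression matrix** — cells × CD molecules with
   POSITIVE / NEGATIVE / UNKNOWN calls. UNKNOWN means *never measured* and
   is a first-class state: it never counts as absence, and collapsing to
   binary requires an explicit policy.
4. **Half-life comparison** — is a gene subset's mRNA/protein turnover
   atypical? Tested with a Monte Carlo resampling null: draw R random
   same-size subsets, compare means, report the add-one empirical p-value
   `(r+1)/(R+1)`.
5. **Gene-set enrichment** — one-sided hypergeometric test
   `p = Σ_{i≥b} C(B,i)·C(N−B,n−i)/C(N,n)` computed in log space, with
   Benjamini–Hochberg step-up FDR adjustment.
6. **Clustering and networks** — agglomerative hierarchical clustering
   (complete/average/single linkage, Euclidean or Jaccard distances,
   deterministic tie-breaking), k-cut cluster labels, Newick export, and
   the weighted marker-commonality graph (edge weight = number of markers
   POSITIVE on both cells) exported as Cytoscape-readable GML.

Because the curated datasets behind such studies are typically not
deposited, `cdome.simulate` generates every input with known ground truth —
class-conditional word distributions for abstracts, planted lineage blocks
with flip noise and missingness for the matrix, log-normal half-lives with
a shifted subset, and planted-term annotations — so the entire pipeline is
testable offline and every recovery claim is checkable against the truth
the generator retained.

## Worked example

```bash
cdome run-all --seed 1 --out-dir demo
```

runs every stage on simulated inputs (a 37-cell × 261-marker matrix with 7
planted lineage groups, an 800-abstract corpus, a 5000-gene half-life
table) and prints the artifact checksums. Inspecting the outputs:

```bash
$ cdome coverage demo/hit_counts.tsv
coverage: 7833/9657 = 0.8111
...

$ python -c "import json; print(json.load(open('demo/triage_metrics.json')))"
{'accuracy': 0.9875, 'fn': 3, 'fp': 2, 'held_out_size': 400,
 'sensitivity': 0.985, 'specificity': 0.99, 'tn': 198, 'tp': 197,
 'train_size': 400}

$ python -c "import json; print(json.load(open('demo/halflife_mc.json'))['p_value'])"
{'mrna': 0.0015998400159984002, 'protein': 0.00019998000199980003}

$ python -c "import json; print(json.load(open('demo/cluster_recovery.json')))"
{'ari_vs_planted': 1.0, 'k': 7, 'linkage': 'complete', 'metric': 'euclidean'}
```

Reading: the classifier trained on a 200+200 draw recovers the held-out
labels almost perfectly under the default signal strength; 81% of
(cell, marker) pairs in this simulation have literature hits (the
generator's missingness setting, not a claim about the real literature);
the planted 30-gene fast-turnover subset is flagged in both channels
(two-sided p ≈ 1.6·10⁻³ for mRNA and 2·10⁻⁴ — the add-one floor at 10,000
resamples — for protein); and the
7-cluster cut reconstructs the planted lineages exactly (adjusted Rand
index 1.0).

Every subcommand also works on externally supplied files in the documented
formats — e.g. `cdome cluster my_matrix.tsv --metric jaccard --k 7` or
`cdome halflife table.tsv cd_genes.txt --tail lower`.

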