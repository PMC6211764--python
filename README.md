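# scunifrac

Statistical comparison of cell-population composition between single-cell
landscapes (scRNA-seq or mass cytometry), using a tree-based weighted
UniFrac distance.

## The problem

Single-cell experiments increasingly span multiple samples — replicates,
conditions, tissues, batches — and the question is no longer "what
populations are in this sample" but "did the population structure *change*":
did a population expand, shrink, appear or vanish? Visual inspection of
t-SNE/UMAP overlays is not quantitative, and correlating mean expression
profiles is biased toward the dominant population. `scunifrac` gives a
single number with a significance test, plus the identity of the
populations that drive it.

## The method

Cells from two samples A and B are pooled, normalized, reduced to a PCA
embedding of highly variable genes, and clustered (average linkage, cut at
k clusters, default k = 10). A rooted tree over the cluster centroids, with
branch lengths from the merge heights, carries each sample as a
distribution of cells over leaves. The distance is the normalized weighted
UniFrac statistic

    D = Σ_i b_i · |A_i/A_T − B_i/B_T|  /  Σ_j d_j · (A_j/A_T + B_j/B_T)

with b_i the length of branch i, A_i/B_i the cells of each sample below it,
and d_j the root-to-leaf depth of leaf j. D = 0 means identical population
structure; D = 1 means no shared populations. Significance comes from
permuting sample labels across the pooled cells with the tree fixed
(p = |{D* ≥ D}|/N), and the same permutations flag the individual branches
whose proportional shift ps_i = |A_i/A_T − B_i/B_T| could not arise by
chance — the distance-driving populations. These can then be characterized
by one-vs-rest differential expression and annotated by Pearson correlation
against a reference cell-type atlas. An n-sample mode produces distance and
p-value matrices, a sample dendrogram, and a counts-per-cluster table;
trees and feature tables export as Newick/TSV for microbiome-ecosystem
tooling.

## Worked example

Two synthetic samples sharing the same two populations but at different
proportions (70/30 in the control, 40/60 after perturbation):

```python
from scunifrac import (PopulationSpec, RunConfig, compare_pair,
                       generate_population_data)

spec = PopulationSpec(n_genes=500, seed=0)
ctrl = generate_population_data(spec, 400, seed=1, weights=[0.7, 0.3],
                                sample_label="control")
pert = generate_population_data(spec, 400, seed=2, weights=[0.4, 0.6],
                                sample_label="perturbed")

cmp = compare_pair(ctrl, pert, RunConfig(seed=0))
print(f"D = {cmp.result.distance:.3f}, p = {cmp.result.p_value:.4f}")
print(cmp.branch_table.query("significant and is_leaf")
      [["node", "ps", "ps_star", "count_a", "count_b"]])
```

prints

```
D = 0.310, p = 0.0000
   node      ps  ps_star  count_a  count_b
0     0  0.2875   0.0725      267      152
1     1  0.3100   0.0700      108      232
```

The distance (0.31) reflects the 30-point proportion swing; p < 0.001 over
1000 label permutations says the shift cannot be explained by chance. Both
leaf clusters are flagged as distance-driving: their observed shifts
(`ps` ≈ 0.29 and 0.31, matching the planted 0.3) far exceed the permutation
thresholds (`ps_star` ≈ 0.07), and the per-sample cell counts show the
direction — cluster 1 shrank from 267 to 152 cells while cluster 2 grew
from 108 to 232. Identical inputs give D = 0 with p = 1; samples with no
shared populations give D = 1.

The same analyses run from the shell:

```
scunifrac pairwise --sample-a control.tsv --sample-b perturbed.tsv \
    --atlas atlas.tsv --outdir out/
scunifrac multi --samples s1.tsv --samples s2.tsv --samples s3.tsv --outdir out/
scunifrac simulate --design design.yaml --outdir sim/
```

`pairwise` writes `summary.json` (distance, p-value, config echo), the
branch table, the cluster tree (Newick), the leaf×sample feature table,
per-cluster signature genes and, with an atlas, the best-matching cell type
per distance-driving cell. Exit codes: 0 success, 2 input error, 3
computation error.

## Scope

The package compares landscapes; it does not align reads, call barcodes,
detect doublets, impute, or correct batch effects (corrected matrices can
be evaluated through the continuous-input path). See `docs/methods.md` for
the model, parameter choices, generator assumptions and limitations.
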