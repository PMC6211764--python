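# Methods

## The model

`scunifrac` quantifies how different two single-cell landscapes are in
*composition* — which cell populations are present and in what proportions —
rather than in average expression. Cells from both samples are pooled and
organized into a rooted hierarchical tree of k clusters; each sample is then
a distribution of cells over the tree, and the dissimilarity is the
normalized weighted UniFrac distance

    D = Σ_i b_i · |A_i/A_T − B_i/B_T|  /  Σ_j d_j · (A_j/A_T + B_j/B_T)

where i runs over all branches (edges above non-root nodes), b_i is the
branch length, A_i and B_i are the numbers of cells of samples A and B in
leaves below branch i, A_T and B_T are the sample totals, j runs over the
leaves, and d_j is the root-to-leaf path length. The denominator is the
average tree depth of a cell and bounds D into [0, 1]: D = 0 when every
branch carries identical proportions of the two samples, and D = 1 exactly
when no branch is shared, because for pure branches the numerator telescopes
to Σ_j d_j(A_j/A_T + B_j/B_T). Note the index set of the two sums differs:
the numerator is over all branches, the denominator over leaves with
root-to-leaf depths. This is the only normalization under which fully
disjoint landscapes reach D = 1; it coincides with the normalized weighted
UniFrac of the microbiome literature, and the implementation is checked in
the test suite against scikit-bio's `weighted_unifrac` as an independent
route.

## Pipeline and parameters

1. **Normalization.** Counts are scaled per cell to a common total
   (`scale_factor`, default the median library size of the pooled cells) and
   transformed with natural-log log1p. The scale factor, pseudocount (1) and
   log base are package choices; any fixed choice gives the same cluster
   structure up to monotone rescaling of expression. Cells with zero library
   size are dropped, never imputed. Continuous inputs (e.g. arcsinh-scaled
   mass-cytometry channels, `continuous=True` / `--no-normalize`) skip this
   step and HVG selection and are embedded directly.
2. **Feature selection.** The `hvg_count` (default 500) genes with the
   largest variance of log-normalized expression are kept; ties break
   lexicographically so the selection is deterministic. A variance-of-log
   criterion was chosen over a mean–variance-trend fit for reproducibility
   and transparency; the interface takes any gene list.
3. **Embedding.** PCA on the mean-centered HVG submatrix (no unit-variance
   scaling, keeping HVG magnitude information) to `n_components` (default 4)
   dimensions. Component signs follow a fixed convention (largest-magnitude
   loading positive), so repeated runs are bitwise identical.
4. **Tree.** Average-linkage agglomerative clustering of cells in the
   embedding (Euclidean), cut to exactly k flat clusters (default k = 10;
   useful range roughly 10–30 — too few clusters blur real structure, very
   many chase noise). A second average-linkage pass over the k cluster
   *centroids* supplies the tree topology and branch lengths: node height is
   half the merge distance, branch length is the height difference to the
   parent. The published description mentions both cell-level clustering and
   a post-hoc centroid tree; the two-stage reading reconciles them and keeps
   stage one pluggable. Coincident centroids would give zero-length
   branches; these are clamped to 1e-12 (warned) so the denominator stays
   positive. k = 1 short-circuits to D = 0.
5. **Significance.** Sample labels are permuted uniformly across the pooled
   cells (N = `n_permutations`, default 1000) with the tree and cluster
   assignments fixed; p = |{D* ≥ D}|/N with ties counted, exactly the
   printed estimator — it can return 0, and `conservative_p` switches to
   (1 + hits)/(1 + N). The same permutations give each branch a null for its
   proportional shift ps_i = |A_i/A_T − B_i/B_T|; a branch is
   distance-driving when ps_i exceeds the per-branch empirical (1 − alpha)
   quantile ps* (alpha default 0.05). Reusing one permutation pass for the
   global and per-branch nulls keeps cost linear in N; whether the original
   implementation used a quantile or max-statistic null is not documented,
   so the quantile rule is a declared choice here.
6. **Annotation.** Per-cluster signatures come from a vectorized one-vs-rest
   Welch t-test on log-normalized values with per-cluster BH adjustment
   (`fdr` 0.05, |lfc| ≥ 0.5); clusters under 3 cells are reported untested.
   A moderated variant (variances shrunk halfway to their mean) is behind a
   flag. This is a self-contained replacement for a limma-style moderated
   comparison — equivalent in purpose (ranked over/under-expressed genes),
   not in numerics. Cell-type matching computes the Pearson correlation of
   each query cell against every reference profile over the shared genes
   (minimum overlap 200 by default), query on the log-normalized scale, with
   `--log-atlas` for atlases shipped as raw means; best match is the argmax,
   ties broken by type-name order; zero-variance cells are unmatchable, not
   errors.

## Multi-sample mode

Every unordered pair is pooled and preprocessed independently (so adding a
sample later changes nothing already computed), with per-pair seeds derived
from the global seed and the sorted label pair; pairs are computed in a
canonical orientation so the matrices are bitwise independent of input
order. The joint clustering is used only for the counts-per-cluster table.
The sample dendrogram is average linkage on the distance matrix. P-values
are reported raw; BH across pairs is an option, off by default.

## The synthetic-data generator

The generator emulates well-separated cell populations. Each population's
latent log-expression is a shared per-gene baseline N(1, 0.5²) plus an
elevation of its private marker genes (25 per population by default); a
cell adds iid N(0, spread²) noise (spread 0.5). The `separation` parameter
(default 10) is the center offset per marker dimension in units of spread.
Counts are Poisson with rates proportional to exp(latent), scaled to
log-normal library sizes (median 2000 UMIs, σ = 0.3); the CyTOF-like mode
emits the latent matrix directly. The generator reproduces multi-population
geometry, proportion shifts, library-size variation and count noise; it does
*not* emulate dropout beyond Poisson sparsity, batch effects, doublets,
continuous differentiation trajectories, or correlated gene programs — so
passing tests demonstrate correctness of the statistic and calibration of
the test under clean population structure, not robustness to every artifact
of real scRNA-seq data.

Mixture experiments follow the two-sample scheme: N1 pure pool-A cells, N2
mixing round(proportion · n2) pool-B cells (half-up rounding) with pool-A
cells, drawn without replacement within a draw and independently across
runs. "Significant" means p < alpha with alpha = 0.05, the conventional
reading, configurable.

## Problem sizes used by the test and acceptance suites

The deterministic extremes (D = 1 disjoint, D = 0 identical) run at 500
cells per sample with 500 genes and full defaults. Calibration/power curves
use 250 cells per side, 300 genes, 200 permutations and 50 runs per
proportion; the 2%-detection experiment uses CyTOF-like pools at 1000 cells
per side, 37 channels and 500 permutations over 20 runs; the k-robustness
sweep uses 300 cells per side over k ∈ {5, 10, 20, 30}. These sizes were
chosen so each experiment retains the qualitative regime of the published
study (clear separation, comparable effect-to-noise ratios) while the whole
suite runs in minutes. `scripts/validate_cytof.py` reruns the full published
scheme (n = 1000, 50 runs) on user-supplied mass-cytometry data.

## Numerical notes and limitations

- All randomness flows through explicit integer seeds; sub-seeds are
  derived by hashing the master seed with the grid coordinates, so results
  are independent of execution order and reproducible bitwise.
- The permutation p-value is conditional on the tree built from the pooled
  data; it is approximately, not exactly, exchangeable under the null and is
  sensitive to tree topology, which is why calibration is verified
  empirically (observed type-I error ≈ nominal at alpha 0.05).
- Average linkage with `cut_tree` is deterministic given input order;
  permuting cells permutes cluster labels but not the partition or the
  distance (verified by canonical-form tests). Exactly tied merge distances
  could in principle change the topology; with continuous embeddings these
  have probability zero.
- The distance compares composition in the *pooled* embedding of the two
  samples being compared; distances from different pairs live on different
  trees and are comparable as dissimilarities, not as coordinates of a
  common geometry.
- Batch effects are not modeled or corrected; comparing samples across
  batches measures technical plus biological difference. Corrected matrices
  can be fed through the continuous-input path to benchmark correction
  methods.
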