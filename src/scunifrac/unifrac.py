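"""The normalized weighted UniFrac distance on a cluster tree, its permutation
test, and per-branch proportional-shift significance.

The distance between samples A and B placed on a rooted tree with branch
lengths is

    D = sum_i b_i * |A_i/A_T - B_i/B_T|  /  sum_j d_j * (A_j/A_T + B_j/B_T)

where i ranges over all branches (non-root nodes), b_i is the length of the
branch above node i, A_i/B_i count the cells of each sample in leaves below
branch i, and the denominator ranges over leaves j with d_j the root-to-leaf
path length — the average cell depth, which normalizes D into [0, 1].
D = 0 when the two samples occupy every branch in identical proportions and
D = 1 exactly when no branch is shared (the numerator then telescopes to the
denominator).

Significance comes from a permutation test: sample labels are shuffled
uniformly across the pooled cells while the tree and cluster assignments
stay fixed, giving a null distribution D*; p = |{D* >= D}| / N.  The same
permutations supply per-branch nulls for the proportional shift
ps_i = |A_i/A_T - B_i/B_T|, and a branch is flagged as distance-driving when
its observed shift exceeds the permutation quantile ps*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import CountMatrix, merge_samples
from .preprocess import Embedding, NormalizedMatrix, embed, normalize, \
    passthrough_embedding, select_hvg
from .tree import BranchCounts, ClusterAssignment, ClusterTree, \
    build_tree, cluster_cells, count_branches

logger = logging.getLogger("scunifrac")


@dataclass
class UniFracResult:
    """Distance, permutation null and per-branch shifts for one comparison."""

    distance: float
    p_value: float
    null_distances: np.ndarray        # (N,)
    n_permutations: int
    branch_shifts: np.ndarray         # (n_nodes,) observed ps_i (root entry 0)
    null_branch_shifts: np.ndarray    # (N, n_nodes) permuted ps_i
    seed: int

    def significant_branches(self, alpha: float = 0.05,
                             adjust: bool = False) -> pd.DataFrame:
        return significant_branches(self, alpha=alpha, adjust=adjust)


def unifrac_distance(tree: ClusterTree | None, counts: BranchCounts) -> float:
    """Evaluate the normalized weighted UniFrac distance on observed counts.

    ``tree=None`` is the k=1 short-circuit: a single cluster holds both
    samples fully, so the distance is identically 0.
    """
    if tree is None:
        return 0.0
    if counts.a_total <= 0 or counts.b_total <= 0:
        raise ValueError("both samples must have at least one cell")
    pa = counts.a / counts.a_total
    pb = counts.b / counts.b_total
    num = float(np.sum(tree.branch_length * np.abs(pa - pb)))  # root length 0
    d_j = tree.root_to_leaf()
    den = float(np.sum(d_j * (pa[: tree.k] + pb[: tree.k])))
    assert den > 0, "denominator must be positive for nonempty samples"
    return num / den


def _shift_and_distance(tree: ClusterTree, leaf_a: np.ndarray,
                        leaf_b: np.ndarray, M: np.ndarray, d_j: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ps_i and D for stacked per-leaf counts (rows = draws)."""
    a_tot = leaf_a.sum(axis=1, keepdims=True)
    b_tot = leaf_b.sum(axis=1, keepdims=True)
    pa = (leaf_a / a_tot) @ M.T   # (N, n_nodes)
    pb = (leaf_b / b_tot) @ M.T
    ps = np.abs(pa - pb)
    num = ps @ tree.branch_length
    den = (pa[:, : tree.k] + pb[:, : tree.k]) @ d_j
    return ps, num / den


def permutation_test(tree: ClusterTree | None, assign: ClusterAssignment,
                     labels: pd.Series, n_permutations: int = 1000,
                     seed: int = 0, conservative_p: bool = False
                     ) -> UniFracResult:
    """Label-permutation null for the UniFrac distance.

    Sample labels are shuffled across all pooled cells (per-sample totals
    preserved); the tree topology, branch lengths and cluster assignments
    are fixed.  ``p = |{D* >= D}| / N`` as printed in the method's
    definition (ties count; can return 0); ``conservative_p`` switches to
    the add-one estimate (1 + count) / (1 + N).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if tree is None:  # k = 1 short-circuit
        warnings.warn("k=1: single cluster, distance identically 0", stacklevel=2)
        n_nodes = 1
        return UniFracResult(0.0, 1.0, np.zeros(n_permutations),
                             n_permutations, np.zeros(n_nodes),
                             np.zeros((n_permutations, n_nodes)), seed)
    counts = count_branches(tree, assign, labels)
    observed = unifrac_distance(tree, counts)
    M = tree.leaf_membership().astype(float)
    d_j = tree.root_to_leaf()
    pa = counts.a / counts.a_total
    pb = counts.b / counts.b_total
    obs_ps = np.abs(pa - pb)

    labels = labels.reindex(assign.cell_ids)
    is_a = (labels == counts.label_a).to_numpy()
    leaf_idx = assign.cluster_of - 1
    rng = np.random.default_rng(seed)
    N = n_permutations
    leaf_a = np.empty((N, tree.k))
    leaf_b = np.empty((N, tree.k))
    perm = is_a.copy()
    for i in range(N):
        rng.shuffle(perm)
        la = np.bincount(leaf_idx[perm], minlength=tree.k)
        leaf_a[i] = la
        leaf_b[i] = np.bincount(leaf_idx, minlength=tree.k) - la
    null_ps, null_d = _shift_and_distance(tree, leaf_a, leaf_b, M, d_j)

    hits = int(np.sum(null_d >= observed))
    p = (1 + hits) / (1 + N) if conservative_p else hits / N
    return UniFracResult(distance=observed, p_value=p, null_distances=null_d,
                         n_permutations=N, branch_shifts=obs_ps,
                         null_branch_shifts=null_ps, seed=seed)


def significant_branches(result: UniFracResult, alpha: float = 0.05,
                         adjust: bool = False) -> pd.DataFrame:
    """Flag branches whose proportional shift exceeds its permutation null.

    For each branch, ps* is the empirical (1 - alpha) quantile of that
    branch's permuted shifts; the branch is significant iff ps_i > ps*.
    A per-branch empirical p-value (1 + #{perm >= obs}) / (N + 1) is also
    reported, optionally BH-adjusted across branches (off by default).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ps = result.branch_shifts
    null = result.null_branch_shifts
    n_nodes = ps.shape[0]
    ps_star = np.quantile(null, 1 - alpha, axis=0)
    p_branch = (1 + (null >= ps[None, :]).sum(axis=0)) / (null.shape[0] + 1)
    table = pd.DataFrame({
        "node": np.arange(n_nodes),
        "ps": ps,
        "ps_star": ps_star,
        "significant": ps > ps_star,
        "p_branch": p_branch,
    })
    if adjust:
        from statsmodels.stats.multitest import multipletests
        table["p_adjusted"] = multipletests(p_branch, method="fdr_bh")[1]
    # the root carries the full cell set on both sides: never a branch
    table.loc[n_nodes - 1, "significant"] = False
    return table


@dataclass
class PairwiseComparison:
    """Everything produced by one two-sample comparison."""

    result: UniFracResult
    tree: ClusterTree | None
    counts: BranchCounts | None
    assignment: ClusterAssignment | None
    embedding: Embedding | None
    normalized: NormalizedMatrix | None
    config: RunConfig
    labels: tuple[str, str]
    branch_table: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.branch_table is None and self.tree is not None:
            self.branch_table = self.result.significant_branches(self.config.alpha)
            self.branch_table["is_leaf"] = self.branch_table["node"] < self.tree.k
            self.branch_table["branch_length"] = self.tree.branch_length
            self.branch_table["count_a"] = self.counts.a
            self.branch_table["count_b"] = self.counts.b


def compare_pair(sample_a: CountMatrix, sample_b: CountMatrix,
                 config: RunConfig | None = None) -> PairwiseComparison:
    """Run the full two-sample pipeline: merge, normalize, HVG, PCA, cluster,
    tree, branch counts, distance, permutation test, branch significance."""
    config = config or RunConfig()
    merged = merge_samples([sample_a, sample_b])
    if config.no_normalize or merged.continuous:
        embedding = passthrough_embedding(merged, d=config.n_components)
        norm = None
    else:
        norm = normalize(merged, config.scale_factor, config.pseudocount)
        hvg = select_hvg(norm, config.hvg_count)
        d = min(config.n_components, len(hvg), merged.n_cells - 1)
        embedding = embed(norm, hvg, d=d)
    k = min(config.k, embedding.n_cells)
    assign = cluster_cells(embedding, k=k, linkage=config.linkage)
    if k == 1:
        tree = counts = None
    else:
        tree = build_tree(embedding, assign, linkage=config.linkage)
        counts = count_branches(tree, assign, merged.sample_labels)
    result = permutation_test(tree, assign, merged.sample_labels,
                              n_permutations=config.n_permutations,
                              seed=config.seed,
                              conservative_p=config.conservative_p)
    labels = (str(sample_a.sample_labels.iloc[0]),
              str(sample_b.sample_labels.iloc[0]))
    return PairwiseComparison(result=result, tree=tree, counts=counts,
                              assignment=assign, embedding=embedding,
                              normalized=norm, config=config, labels=labels)
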