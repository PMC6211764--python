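"""Hierarchical clustering of pooled cells and the cluster tree over centroids.

Two stages: (1) average-linkage agglomerative clustering of cells in the
embedding space, cut to exactly ``k`` flat clusters; (2) a fresh
average-linkage dendrogram over the ``k`` cluster centroids supplies the
rooted tree topology and branch lengths consumed by the UniFrac distance.

Node indexing follows the scipy linkage convention: leaves are
``0..k-1`` (cluster ``j`` is node ``j-1``), internal nodes ``k..2k-2``,
the root being the final merge ``2k-2``.  A node's height is half its merge
distance (so two centroids at distance ``2h`` merge into a root at height
``h``); the branch above a node has length ``height(parent) - height(node)``.
Zero-length branches (coincident centroids) are clamped to a small epsilon
so the UniFrac denominator stays positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .preprocess import Embedding

logger = logging.getLogger("scunifrac")

ZERO_BRANCH_EPS = 1e-12
W_ZERO_BRANCH = "ZERO_LENGTH_BRANCH"


@dataclass
class ClusterAssignment:
    """Flat assignment of every pooled cell to a cluster in 1..k."""

    cell_ids: pd.Index
    cluster_of: np.ndarray  # int array in 1..k, aligned with cell_ids
    k: int

    def __post_init__(self) -> None:
        present = np.unique(self.cluster_of)
        if len(self.cell_ids) != len(self.cluster_of):
            raise ValueError("cell_ids and cluster_of length mismatch")
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError(f"clusters must cover 1..{self.k}; found {present}")

    def sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_of, minlength=self.k + 1)[1:]


@dataclass
class ClusterTree:
    """Rooted tree over k leaf clusters with branch lengths.

    Arrays are indexed by node (0..2k-2).  The root has parent -1 and no
    incoming branch; the branch set is every non-root node's incoming edge
    (n_branches = 2k-2).
    """

    k: int
    parent: np.ndarray          # (2k-1,), -1 at root
    branch_length: np.ndarray   # (2k-1,), 0.0 at root
    height: np.ndarray          # (2k-1,)
    leaf_centroids: np.ndarray  # (k, d)
    children: list[list[int]] = field(repr=False, default=None)  # type: ignore

    def __post_init__(self) -> None:
        n = 2 * self.k - 1
        if self.children is None:
            ch: list[list[int]] = [[] for _ in range(n)]
            for node, par in enumerate(self.parent):
                if par >= 0:
                    ch[par].append(node)
            self.children = ch

    @property
    def n_nodes(self) -> int:
        return 2 * self.k - 1

    @property
    def n_branches(self) -> int:
        return 2 * self.k - 2

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def root_to_leaf(self) -> np.ndarray:
        """Summed branch lengths from the root to each leaf (d_j)."""
        out = np.zeros(self.k)
        for leaf in range(self.k):
            node, total = leaf, 0.0
            while self.parent[node] >= 0:
                total += self.branch_length[node]
                node = self.parent[node]
            out[leaf] = total
        return out

    def leaf_membership(self) -> np.ndarray:
        """Boolean (n_nodes, k) matrix: M[i, j] iff leaf j descends from node i
        (a node descends from itself)."""
        M = np.zeros((self.n_nodes, self.k), dtype=bool)
        M[np.arange(self.k), np.arange(self.k)] = True
        for node in range(self.k, self.n_nodes):
            for c in self.children[node]:
                M[node] |= M[c]
        return M

    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            if node < self.k:
                return f"cluster{node + 1}:{self.branch_length[node]:.10g}"
            inner = ",".join(fmt(c) for c in self.children[node])
            if node == self.root:
                return f"({inner})"
            return f"({inner}):{self.branch_length[node]:.10g}"

        return fmt(self.root) + ";"


@dataclass
class BranchCounts:
    """Per-branch descendant cell counts for samples A and B."""

    a: np.ndarray  # (n_nodes,) sample-A cells below each node
    b: np.ndarray
    a_total: int
    b_total: int
    label_a: str
    label_b: str


def cluster_cells(emb: Embedding, k: int = 10, linkage: str = "average",
                  metric: str = "euclidean") -> ClusterAssignment:
    """Agglomerative clustering of cells, cut to exactly k flat clusters."""
    n = emb.n_cells
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells ({n})")
    if k == n:
        return ClusterAssignment(emb.cell_ids, np.arange(1, n + 1), k)
    Z = hierarchy.linkage(emb.coords, method=linkage, metric=metric)
    flat = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    # relabel to 1..k in order of first appearance for determinism
    _, first = np.unique(flat, return_index=True)
    order = {old: new + 1 for new, old in
             enumerate(flat[np.sort(first)])}
    labels = np.array([order[c] for c in flat], dtype=int)
    return ClusterAssignment(emb.cell_ids, labels, k)


def build_tree(emb: Embedding, assign: ClusterAssignment,
               linkage: str = "average") -> ClusterTree:
    """Average-linkage tree over cluster centroids.

    Raises for k = 1 — a one-leaf tree has no branches and callers should
    short-circuit to distance 0.
    """
    k = assign.k
    if k < 2:
        raise ValueError("tree undefined for k=1; distance is identically 0")
    centroids = np.vstack([
        emb.coords[assign.cluster_of == j].mean(axis=0) for j in range(1, k + 1)
    ])
    Z = hierarchy.linkage(centroids, method=linkage, metric="euclidean")
    n_nodes = 2 * k - 1
    parent = np.full(n_nodes, -1, dtype=int)
    height = np.zeros(n_nodes)
    for i in range(k - 1):
        node = k + i
        left, right = int(Z[i, 0]), int(Z[i, 1])
        parent[left] = parent[right] = node
        height[node] = Z[i, 2] / 2.0
    blen = np.zeros(n_nodes)
    nonroot = parent >= 0
    blen[nonroot] = height[parent[nonroot]] - height[nonroot]
    if (blen[nonroot] <= 0).any():
        n_bad = int((blen[nonroot] <= 0).sum())
        msg = (f"[{W_ZERO_BRANCH}] {n_bad} zero/negative-length branch(es) "
               f"clamped to {ZERO_BRANCH_EPS}")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        blen[nonroot] = np.maximum(blen[nonroot], ZERO_BRANCH_EPS)
    return ClusterTree(k=k, parent=parent, branch_length=blen,
                       height=height, leaf_centroids=centroids)


def count_branches(tree: ClusterTree, assign: ClusterAssignment,
                   labels: pd.Series) -> BranchCounts:
    """Per-branch per-sample descendant cell counts (A_i, B_i).

    ``labels`` maps every pooled cell ID to one of exactly two sample labels.
    """
    labels = labels.reindex(assign.cell_ids)
    if labels.isna().any():
        raise ValueError("label map does not cover every pooled cell")
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two sample labels, found {uniq}")
    label_a, label_b = uniq
    is_a = (labels == label_a).to_numpy()
    leaf_idx = assign.cluster_of - 1
    leaf_a = np.bincount(leaf_idx[is_a], minlength=tree.k)
    leaf_b = np.bincount(leaf_idx[~is_a], minlength=tree.k)
    if leaf_a.sum() == 0 or leaf_b.sum() == 0:
        raise ValueError("a sample has zero cells; distance undefined")
    M = tree.leaf_membership()
    return BranchCounts(a=M @ leaf_a, b=M @ leaf_b,
                        a_total=int(leaf_a.sum()), b_total=int(leaf_b.sum()),
                        label_a=str(label_a), label_b=str(label_b))


def export_tree(tree: ClusterTree, counts: BranchCounts,
                path: str | Path) -> tuple[Path, Path]:
    """Write the cluster tree (Newick) and the leaf x sample abundance table
    (TSV feature table, consumable by microbiome tooling such as QIIME).

    ``path`` is a directory; returns (newick_path, table_path).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    nwk = path / "cluster_tree.nwk"
    nwk.write_text(tree.to_newick() + "\n")
    table = pd.DataFrame(
        {counts.label_a: counts.a[: tree.k], counts.label_b: counts.b[: tree.k]},
        index=[f"cluster{j + 1}" for j in range(tree.k)])
    table.index.name = "cluster"
    tbl = path / "feature_table.tsv"
    table.to_csv(tbl, sep="\t")
    return nwk, tbl
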