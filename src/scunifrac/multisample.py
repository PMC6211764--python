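"""Multi-sample mode: pairwise distance/significance matrices, a sample
dendrogram, and a joint counts-per-cluster table.

Each unordered pair is pooled, preprocessed and clustered on its own (the
pairwise report stays valid when samples are added later); the joint
clustering is used only for the counts table.  Per-pair seeds are derived
deterministically from the global seed and the sorted pair labels, so
results do not depend on execution order.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .config import RunConfig
from .io import CountMatrix, merge_samples
from .preprocess import embed, normalize, passthrough_embedding, select_hvg
from .tree import cluster_cells
from .unifrac import PairwiseComparison, compare_pair


def derive_seed(seed: int, *parts: str) -> int:
    """Deterministic sub-seed (< 2**31) from a master seed and string parts."""
    h = hashlib.blake2s(("|".join([str(seed), *parts])).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance and p-value matrices over n samples."""

    labels: list[str]
    distance: pd.DataFrame  # n x n, zero diagonal
    p_value: pd.DataFrame   # n x n, unit diagonal
    pairs: dict[tuple[str, str], PairwiseComparison]


def compare_all(samples: list[CountMatrix],
                config: RunConfig | None = None) -> DistanceMatrix:
    """Run every unordered sample pair through the pairwise pipeline."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    config = config or RunConfig()
    labels = [str(s.sample_labels.iloc[0]) for s in samples]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate sample labels: {labels}")
    D = pd.DataFrame(0.0, index=labels, columns=labels)
    P = pd.DataFrame(1.0, index=labels, columns=labels)
    pairs: dict[tuple[str, str], PairwiseComparison] = {}
    for (i, a), (j, b) in itertools.combinations(enumerate(samples), 2):
        la, lb = labels[i], labels[j]
        key = tuple(sorted((la, lb)))
        if la > lb:  # canonical orientation: results independent of input order
            a, b, la, lb = b, a, lb, la
        pair_cfg = config.replace(seed=derive_seed(config.seed, *key))
        try:
            cmp = compare_pair(a, b, pair_cfg)
        except Exception as exc:
            raise RuntimeError(f"pair ({la}, {lb}) failed: {exc}") from exc
        pairs[key] = cmp
        D.loc[la, lb] = D.loc[lb, la] = cmp.result.distance
        P.loc[la, lb] = P.loc[lb, la] = cmp.result.p_value
    return DistanceMatrix(labels=labels, distance=D, p_value=P, pairs=pairs)


def adjust_pvalues(dm: DistanceMatrix, method: str = "fdr_bh") -> pd.DataFrame:
    """BH-adjust the off-diagonal p-values across all sample pairs.

    Raw p-values are reported by default; this helper is for designs with
    many pairs where family-wise control matters.
    """
    from statsmodels.stats.multitest import multipletests
    n = len(dm.labels)
    iu = np.triu_indices(n, k=1)
    raw = dm.p_value.to_numpy()[iu]
    adj = multipletests(raw, method=method)[1]
    out = np.ones((n, n))
    out[iu] = adj
    out.T[iu] = adj
    return pd.DataFrame(out, index=dm.labels, columns=dm.labels)


def sample_dendrogram(dm: DistanceMatrix,
                      linkage: str = "average") -> tuple[str, np.ndarray]:
    """Average-linkage clustering of samples on the distance matrix.

    Returns the Newick string and the scipy linkage matrix.
    """
    labels = dm.labels
    if len(labels) == 2:
        h = float(dm.distance.iloc[0, 1])
        return f"({labels[0]}:{h / 2:.10g},{labels[1]}:{h / 2:.10g});", \
            np.array([[0.0, 1.0, h, 2.0]])
    condensed = squareform(dm.distance.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    n = len(labels)
    height = np.zeros(2 * n - 1)
    height[n:] = Z[:, 2] / 2.0

    def fmt(node: int, parent_h: float) -> str:
        blen = parent_h - height[node]
        if node < n:
            return f"{labels[node]}:{blen:.10g}"
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        inner = f"({fmt(left, height[node])},{fmt(right, height[node])})"
        return inner if parent_h == height[node] else f"{inner}:{blen:.10g}"

    root = 2 * n - 2
    return fmt(root, height[root]) + ";", Z


def joint_counts_table(samples: list[CountMatrix],
                       config: RunConfig | None = None) -> pd.DataFrame:
    """One joint clustering over all samples pooled; cell counts per joint
    cluster per sample (columns sum to each sample's cell count)."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    config = config or RunConfig()
    merged = merge_samples(samples)
    if config.no_normalize or merged.continuous:
        embedding = passthrough_embedding(merged, d=config.n_components)
    else:
        norm = normalize(merged, config.scale_factor, config.pseudocount)
        hvg = select_hvg(norm, config.hvg_count)
        d = min(config.n_components, len(hvg), merged.n_cells - 1)
        embedding = embed(norm, hvg, d=d)
    k = min(config.k, embedding.n_cells)
    assign = cluster_cells(embedding, k=k, linkage=config.linkage)
    labels = merged.sample_labels
    table = pd.crosstab(
        pd.Series(assign.cluster_of, index=assign.cell_ids, name="cluster"),
        labels.rename("sample"))
    table.index = [f"cluster{j}" for j in table.index]
    sample_order = [str(s.sample_labels.iloc[0]) for s in samples]
    return table.reindex(columns=sample_order, fill_value=0)
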