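import numpy as np
import pandas as pd
import pytest

from scunifrac import CountMatrix, Embedding
from scunifrac.tree import ClusterAssignment, ClusterTree


def make_counts(values, genes=None, cells=None, label="sample"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=genes, columns=cells), label)


def make_embedding(coords, labels=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    cells = pd.Index([f"c{i}" for i in range(n)])
    lab = pd.Series(labels if labels is not None else "s", index=cells)
    return Embedding(coords=coords, cell_ids=cells, d=coords.shape[1],
                     hvg_ids=[], explained_variance=np.zeros(coords.shape[1]),
                     sample_labels=lab)


def make_tree(parent, branch_length, k):
    """Hand-built ClusterTree from a parent array and branch lengths."""
    parent = np.asarray(parent, dtype=int)
    blen = np.asarray(branch_length, dtype=float)
    n = 2 * k - 1
    height = np.zeros(n)
    # heights by accumulating lengths upward from leaves (ultrametric not required)
    for node in range(k, n):
        child = int(np.where(parent == node)[0][0])
        height[node] = height[child] + blen[child]
    return ClusterTree(k=k, parent=parent, branch_length=blen, height=height,
                       leaf_centroids=np.zeros((k, max(1, 1))))


def star_tree(lengths):
    """Star tree: k leaves all children of the root."""
    k = len(lengths)
    # represent as caterpillar with zero-length internals when k > 2
    if k == 2:
        return make_tree([2, 2, -1], list(lengths) + [0.0], 2)
    raise NotImplementedError


@pytest.fixture
def two_blob_counts():
    """Two well-separated 50-cell blobs as raw counts (planted markers)."""
    from scunifrac import PopulationSpec, generate_population_data
    spec = PopulationSpec(n_genes=200, n_markers=20, seed=7)
    a = generate_population_data(spec, 100, seed=1, weights=[1, 0], sample_label="A")
    b = generate_population_data(spec, 100, seed=2, weights=[0, 1], sample_label="B")
    return a, b


def brute_force_unifrac(tree, leaf_a, leaf_b):
    """Independent evaluation of the distance equation by explicit loops.

    Walks every non-root branch, recounts its descendant leaves by path
    traversal, and sums the equation term by term.  Shares no code with the
    implementation under test.
    """
    k = tree.k
    leaf_a = np.asarray(leaf_a, float)
    leaf_b = np.asarray(leaf_b, float)
    at, bt = leaf_a.sum(), leaf_b.sum()

    def leaves_below(node):
        if node < k:
            return [node]
        out = []
        for cand in range(2 * k - 1):
            if tree.parent[cand] == node:
                out.extend(leaves_below(cand))
        return out

    num = 0.0
    for node in range(2 * k - 1):
        if tree.parent[node] < 0:
            continue
        below = leaves_below(node)
        ai = sum(leaf_a[j] for j in below)
        bi = sum(leaf_b[j] for j in below)
        num += tree.branch_length[node] * abs(ai / at - bi / bt)
    den = 0.0
    for j in range(k):
        d_j, node = 0.0, j
        while tree.parent[node] >= 0:
            d_j += tree.branch_length[node]
            node = tree.parent[node]
        den += d_j * (leaf_a[j] / at + leaf_b[j] / bt)
    return num / den
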