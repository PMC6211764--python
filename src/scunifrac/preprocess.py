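"""Library-size normalization, highly-variable-gene selection and PCA embedding.

The pipeline mirrors common scRNA-seq practice: per-cell counts are scaled
to a common total (default: the median library size of the pooled cells),
log-transformed with a pseudocount of 1 (natural log), the top-n genes by
variance of the log-normalized values are retained, and cells are embedded
by PCA on the mean-centered HVG submatrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .io import CountMatrix

logger = logging.getLogger("scunifrac")

W_FEW_GENES = "HVG_FEWER_GENES"


@dataclass
class NormalizedMatrix:
    """Log-scale expression: value = log(pseudocount + scale_factor * x / libsize)."""

    values: pd.DataFrame  # genes x cells
    scale_factor: float
    pseudocount: float
    sample_labels: pd.Series

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class Embedding:
    """Cells x d principal-component scores.

    ``explained_variance`` holds the per-component variances, nonincreasing.
    Component signs are fixed by requiring the gene loading of largest
    magnitude to be positive, so repeated runs are bitwise identical.
    """

    coords: np.ndarray  # (n_cells, d)
    cell_ids: pd.Index
    d: int
    hvg_ids: list[str]
    explained_variance: np.ndarray
    sample_labels: pd.Series

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


def normalize(counts: CountMatrix, scale_factor: float | None = None,
              pseudocount: float = 1.0) -> NormalizedMatrix:
    """Per-cell library-size normalization followed by a log transform.

    value(g, c) = log(pseudocount + scale_factor * raw(g, c) / library_size(c))

    With ``scale_factor=None`` the median library size of the pooled cells
    is used, which keeps values on roughly the raw count scale.
    """
    lib = counts.library_sizes().to_numpy()
    if scale_factor is None:
        scale_factor = float(np.median(lib))
    if scale_factor <= 0 or pseudocount <= 0:
        raise ValueError("scale_factor and pseudocount must be positive")
    scaled = counts.values.to_numpy() * (scale_factor / lib)
    vals = np.log(pseudocount + scaled)
    if pseudocount == 1.0:  # log1p is exact at 0
        vals = np.log1p(scaled)
    return NormalizedMatrix(
        pd.DataFrame(vals, index=counts.gene_ids, columns=counts.cell_ids),
        scale_factor, pseudocount, counts.sample_labels.copy())


def select_hvg(norm: NormalizedMatrix, n_genes: int = 500) -> list[str]:
    """Top-``n_genes`` gene IDs by variance of log-normalized expression.

    Ties are broken lexicographically by gene ID so the selection is a
    deterministic function of the input.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    var = norm.values.var(axis=1, ddof=1)
    if n_genes >= len(var):
        if n_genes > len(var):
            msg = (f"[{W_FEW_GENES}] requested {n_genes} HVGs but only "
                   f"{len(var)} genes present; returning all")
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
        n_genes = len(var)
    order = sorted(var.index, key=lambda g: (-var[g], str(g)))
    return [str(g) for g in order[:n_genes]]


def embed(norm: NormalizedMatrix, hvg: list[str], d: int = 4) -> Embedding:
    """PCA scores of the pooled cells on the HVG submatrix.

    Genes are mean-centered (no unit-variance scaling); components are
    ordered by explained variance with a deterministic sign convention.
    Raises if ``d`` exceeds the achievable rank.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    X = norm.values.loc[hvg].to_numpy().T  # cells x genes
    n_cells = X.shape[0]
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = scipy.linalg.svd(X, full_matrices=False)
    tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if d > rank:
        raise ValueError(f"d={d} exceeds achievable rank {rank}")
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(len(s)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip
    coords = (U[:, :d] * s[:d])
    expl = (s[:d] ** 2) / max(n_cells - 1, 1)
    return Embedding(coords=coords, cell_ids=norm.cell_ids, d=d,
                     hvg_ids=list(hvg), explained_variance=expl,
                     sample_labels=norm.sample_labels.copy())


def passthrough_embedding(counts: CountMatrix, d: int | None = 4) -> Embedding:
    """Embed continuous (e.g. mass-cytometry) data directly, skipping
    normalization and HVG selection.

    Values are taken as-is; PCA to ``d`` components (capped at the feature
    count) supplies the coordinate space.
    """
    norm = NormalizedMatrix(counts.values.astype(float), 1.0, 1.0,
                            counts.sample_labels.copy())
    genes = [str(g) for g in counts.gene_ids]
    if d is None:
        d = len(genes)
    d = min(d, len(genes))
    return embed(norm, genes, d=d)
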