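"""Characterizing distance-driving populations.

Two tools: per-cluster differential-expression signatures (a vectorized
one-vs-rest Welch t-test on log-normalized values, BH-adjusted per cluster,
with an optional variance-moderation variant), and cell-type annotation by
Pearson correlation of each query cell against the column profiles of a
reference expression atlas (e.g. a cell-type atlas of mean transcriptomes),
computed over the genes shared between query and atlas.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix
from .tree import ClusterAssignment

logger = logging.getLogger("scunifrac")

W_DUP_ATLAS_GENE = "ATLAS_DUPLICATE_GENES"


@dataclass
class ReferenceAtlas:
    """Genes x cell-type mean expression profiles."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        if self.profiles.empty:
            raise ValueError("empty atlas table")
        vals = self.profiles.to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or not np.all(np.isfinite(vals)):
            raise ValueError("atlas contains non-numeric or non-finite entries")
        if self.profiles.columns.duplicated().any():
            raise ValueError("duplicate cell-type names in atlas")
        if self.profiles.index.duplicated().any():
            raise ValueError("duplicate gene IDs in atlas (collapse before use)")

    @property
    def type_names(self) -> list[str]:
        return [str(c) for c in self.profiles.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.profiles.index


def read_atlas(path: str | Path, log_transform: bool = False) -> ReferenceAtlas:
    """Read a dense genes x cell-types table (TSV/CSV by extension).

    Duplicate gene rows are collapsed by mean with a warning.  With
    ``log_transform`` the profiles are log1p-transformed, for atlases
    distributed as raw mean counts.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"empty atlas table: {path}")
    df.index = df.index.astype(str)
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise ValueError("atlas contains non-numeric entries")
    if df.index.duplicated().any():
        n = int(df.index.duplicated().sum())
        msg = f"[{W_DUP_ATLAS_GENE}] collapsing {n} duplicate atlas gene row(s) by mean"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        df = df.groupby(level=0, sort=False).mean()
    if log_transform:
        df = np.log1p(df)
    return ReferenceAtlas(df.astype(float))


def cluster_signatures(norm: NormalizedMatrix, assign: ClusterAssignment,
                       fdr: float = 0.05, min_abs_lfc: float = 0.5,
                       min_cells: int = 3, moderate: bool = False
                       ) -> pd.DataFrame:
    """One-vs-rest differential expression per cluster.

    Per cluster, every gene is tested cluster-vs-rest with a Welch t-test on
    log-normalized values; the effect size is the difference of means (a log
    fold-change).  P-values are BH-adjusted within each cluster; genes with
    adjusted p < ``fdr`` and |lfc| >= ``min_abs_lfc`` are flagged as
    signature, split over/under.  Clusters with fewer than ``min_cells``
    cells are reported untested (NaN statistics).  ``moderate`` shrinks
    per-gene variances halfway toward their mean, a light-touch analog of
    moderated statistics for small groups.
    """
    if assign.k < 2:
        raise ValueError("need at least two clusters")
    X = norm.values.to_numpy()  # genes x cells
    genes = norm.gene_ids
    rows = []
    for j in range(1, assign.k + 1):
        mask = assign.cluster_of == j
        n1, n2 = int(mask.sum()), int((~mask).sum())
        lfc = X[:, mask].mean(axis=1) - X[:, ~mask].mean(axis=1)
        if n1 < min_cells or n2 < min_cells:
            rows.append(pd.DataFrame({
                "cluster": j, "gene": genes, "lfc": lfc, "t": np.nan,
                "p": np.nan, "p_adjusted": np.nan, "signature": False,
                "direction": np.where(lfc >= 0, "over", "under"),
                "tested": False}))
            continue
        v1 = X[:, mask].var(axis=1, ddof=1)
        v2 = X[:, ~mask].var(axis=1, ddof=1)
        if moderate:
            v1 = 0.5 * (v1 + v1.mean())
            v2 = 0.5 * (v2 + v2.mean())
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / np.sqrt(se2)
            df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        t = np.where(se2 == 0, 0.0, t)
        df = np.where(np.isfinite(df) & (df > 0), df, 1.0)
        p = 2 * stats.t.sf(np.abs(t), df)
        p_adj = multipletests(p, method="fdr_bh")[1]
        rows.append(pd.DataFrame({
            "cluster": j, "gene": genes, "lfc": lfc, "t": t, "p": p,
            "p_adjusted": p_adj,
            "signature": (p_adj < fdr) & (np.abs(lfc) >= min_abs_lfc),
            "direction": np.where(lfc >= 0, "over", "under"),
            "tested": True}))
    return pd.concat(rows, ignore_index=True)


def match_to_atlas(norm: NormalizedMatrix, cells: list[str],
                   atlas: ReferenceAtlas, min_overlap: int = 200
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Pearson correlation of each query cell against every atlas profile.

    Correlations are computed over the gene intersection; the best match per
    cell is the argmax correlation, ties broken by cell-type name order.
    Cells with zero expression variance over the intersection are reported
    unmatchable (NaN row) rather than raising.  Returns (correlation table
    cells x types, best-match Series).
    """
    shared = norm.gene_ids.intersection(atlas.gene_ids)
    if len(shared) < min_overlap:
        raise ValueError(
            f"gene overlap with atlas ({len(shared)}) below minimum {min_overlap}")
    Q = norm.values.loc[shared, list(cells)].to_numpy().T  # cells x genes
    R = atlas.profiles.loc[shared].to_numpy()              # genes x types
    Qc = Q - Q.mean(axis=1, keepdims=True)
    Rc = R - R.mean(axis=0, keepdims=True)
    qn = np.linalg.norm(Qc, axis=1)
    rn = np.linalg.norm(Rc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Qc @ Rc) / np.outer(qn, rn)
    corr[qn == 0, :] = np.nan  # flat cells: unmatchable
    corr[:, rn == 0] = np.nan
    types = sorted(atlas.type_names)
    table = pd.DataFrame(corr, index=list(cells),
                         columns=atlas.type_names)[types]
    valid = ~table.isna().all(axis=1)
    best = pd.Series(np.nan, index=table.index, dtype=object)
    if valid.any():
        best[valid] = table.loc[valid].idxmax(axis=1)
    return table, best
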