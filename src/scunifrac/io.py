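"""Reading, validation and merging of single-cell count matrices.

Counts are stored genes x cells in a pandas DataFrame, with a per-cell
sample label kept alongside.  Two on-disk layouts are supported:

* MatrixMarket triplet: ``matrix.mtx`` plus ``genes.tsv`` and
  ``barcodes.tsv`` sidecars (the CellRanger-style layout), and
* a dense CSV/TSV table with gene IDs in the first column and cell IDs in
  the header (genes-as-rows by default; an explicit flag flips it).

Cells with a zero library size are dropped at validation time with a
warning: per-cell normalization is undefined for them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("scunifrac")

# stable, greppable warning codes
W_ZERO_LIB = "ZERO_LIB_CELLS"
W_GENE_OVERLAP = "GENE_OVERLAP_LOW"


class CountMatrixError(ValueError):
    """Invalid count-matrix input (negative/non-finite values, duplicate IDs...)."""


@dataclass
class CountMatrix:
    """Raw nonnegative gene x cell UMI (or event) counts for one or more samples.

    Parameters
    ----------
    values
        DataFrame of shape (n_genes, n_cells); index = gene IDs,
        columns = cell IDs.
    sample_labels
        Series mapping each cell ID to its sample label.  A plain string is
        broadcast to all cells.
    continuous
        Continuous channel data (e.g. mass-cytometry intensities): values
        may be negative and the zero-library rule does not apply.  Such
        matrices take the no-normalize path through the pipeline.
    """

    values: pd.DataFrame
    sample_labels: pd.Series = field(default=None)  # type: ignore[assignment]
    continuous: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.sample_labels, str) or self.sample_labels is None:
            label = self.sample_labels if self.sample_labels is not None else "sample"
            self.sample_labels = pd.Series(label, index=self.values.columns)
        self._validate()

    def _validate(self) -> None:
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise CountMatrixError("count matrix contains non-finite entries")
        if not self.continuous and (vals < 0).any():
            raise CountMatrixError("count matrix contains negative entries")
        dup_genes = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_genes) > 0:
            raise CountMatrixError(
                f"duplicate gene IDs: {sorted(map(str, dup_genes))[:10]}"
            )
        if self.values.columns.duplicated().any():
            raise CountMatrixError("duplicate cell IDs within sample")
        lib = vals.sum(axis=0)
        empty = lib <= 0 if not self.continuous else np.zeros(vals.shape[1], bool)
        if empty.any():
            n = int(empty.sum())
            msg = f"[{W_ZERO_LIB}] dropping {n} cell(s) with zero library size"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            keep = self.values.columns[~empty]
            self.values = self.values[keep]
            self.sample_labels = self.sample_labels.loc[keep]
        self.sample_labels = self.sample_labels.reindex(self.values.columns)

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)

    def subset_cells(self, cells) -> "CountMatrix":
        return CountMatrix(self.values[list(cells)].copy(),
                           self.sample_labels.loc[list(cells)].copy(),
                           continuous=self.continuous)


def read_counts(path: str | Path, format: str = "auto", *,
                sample_label: str | None = None,
                genes_as_rows: bool = True) -> CountMatrix:
    """Read a count matrix from disk.

    ``format`` is one of ``mtx-triplet``, ``dense-table`` or ``auto``
    (decided from the path: a directory or ``.mtx`` file means triplet).
    For dense tables the orientation defaults to genes-as-rows; pass
    ``genes_as_rows=False`` for cells-as-rows tables — orientation is never
    guessed silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "mtx-triplet" if (path.is_dir() or path.suffix == ".mtx") else "dense-table"
    if sample_label is None:
        sample_label = path.stem if path.is_file() else path.name

    if format == "mtx-triplet":
        df = _read_mtx_triplet(path)
    elif format == "dense-table":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if not genes_as_rows:
            df = df.T
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    else:
        raise ValueError(f"unknown format {format!r}")
    return CountMatrix(df.astype(float), sample_label)


def _read_mtx_triplet(path: Path) -> pd.DataFrame:
    if path.is_file():
        path = path.parent
    mtx = path / "matrix.mtx"
    genes = path / "genes.tsv"
    barcodes = path / "barcodes.tsv"
    for p in (mtx, genes, barcodes):
        if not p.exists():
            raise FileNotFoundError(f"missing sidecar file {p}")
    mat = scipy.io.mmread(mtx)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    gene_ids = pd.read_csv(genes, sep="\t", header=None)[0].astype(str)
    cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str)
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise CountMatrixError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(gene_ids)} genes, {len(cell_ids)} barcodes)")
    return pd.DataFrame(np.asarray(mat, dtype=float),
                        index=gene_ids.values, columns=cell_ids.values)


def write_mtx_triplet(counts: CountMatrix, path: str | Path) -> None:
    """Write a CountMatrix as a matrix.mtx / genes.tsv / barcodes.tsv triplet."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx",
                     scipy.sparse.coo_matrix(counts.values.to_numpy()))
    pd.Series(counts.gene_ids).to_csv(path / "genes.tsv", sep="\t",
                                      header=False, index=False)
    pd.Series(counts.cell_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                      header=False, index=False)


def merge_samples(samples: list[CountMatrix]) -> CountMatrix:
    """Pool two or more samples on their shared genes.

    Cell IDs are made unique by prefixing with the sample label
    (``label:cell``); per-cell sample labels are preserved.  Gene order
    follows the first sample restricted to the intersection.  Warns when the
    intersection covers less than half of any input's genes.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples to merge")
    labels = [str(s.sample_labels.iloc[0]) for s in samples]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate sample labels: {labels}")

    shared = set(samples[0].gene_ids)
    for s in samples[1:]:
        shared &= set(s.gene_ids)
    if not shared:
        raise ValueError("empty gene intersection between samples")
    genes = [g for g in samples[0].gene_ids if g in shared]
    for s, lab in zip(samples, labels):
        if len(shared) < 0.5 * s.n_genes:
            msg = (f"[{W_GENE_OVERLAP}] gene intersection ({len(shared)}) covers "
                   f"<50% of sample {lab!r} ({s.n_genes} genes)")
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)

    blocks, label_series = [], []
    for s, lab in zip(samples, labels):
        block = s.values.loc[genes].copy()
        block.columns = [f"{lab}:{c}" for c in block.columns]
        blocks.append(block)
        label_series.append(pd.Series(lab, index=block.columns))
    merged = pd.concat(blocks, axis=1)
    return CountMatrix(merged, pd.concat(label_series),
                       continuous=any(s.continuous for s in samples))
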