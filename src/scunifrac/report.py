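"""Machine-readable reports for pairwise and multi-sample runs.

The pairwise report is a JSON summary (distance, p-value, seed, config
echo) plus TSV/Newick side files: the branch table, the cluster tree, the
leaf x sample feature table, per-cluster signatures and, when an atlas is
supplied, the cell-type match table.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import ReferenceAtlas, cluster_signatures, match_to_atlas
from .multisample import DistanceMatrix, sample_dendrogram
from .tree import export_tree
from .unifrac import PairwiseComparison

logger = logging.getLogger("scunifrac")


def write_pairwise_report(cmp: PairwiseComparison, outdir: str | Path,
                          atlas: ReferenceAtlas | None = None,
                          min_atlas_overlap: int = 200) -> dict:
    """Write the full pairwise report into ``outdir``; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {
        "sample_a": cmp.labels[0],
        "sample_b": cmp.labels[1],
        "distance": cmp.result.distance,
        "p_value": cmp.result.p_value,
        "n_permutations": cmp.result.n_permutations,
        "seed": cmp.result.seed,
        "k": cmp.tree.k if cmp.tree is not None else 1,
        "config": cmp.config.to_dict(),
    }
    cmp.config.write_echo(outdir / "config_echo.json")
    if cmp.tree is not None:
        export_tree(cmp.tree, cmp.counts, outdir)
        cmp.branch_table.to_csv(outdir / "branch_table.tsv", sep="\t", index=False)
        sig_leaves = cmp.branch_table.query("significant and is_leaf")["node"]
        summary["significant_clusters"] = [f"cluster{n + 1}" for n in sig_leaves]
        if cmp.normalized is not None:
            sig = cluster_signatures(cmp.normalized, cmp.assignment,
                                     fdr=cmp.config.alpha)
            sig.to_csv(outdir / "signatures.tsv", sep="\t", index=False)
            if atlas is not None:
                _write_matches(cmp, atlas, outdir, summary, min_atlas_overlap)
    np.savetxt(outdir / "null_distances.tsv", cmp.result.null_distances)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    logger.info("pairwise report written to %s (D=%.4f, p=%.4g)",
                outdir, summary["distance"], summary["p_value"])
    return summary


def _write_matches(cmp: PairwiseComparison, atlas: ReferenceAtlas,
                   outdir: Path, summary: dict, min_overlap: int) -> None:
    driving = cmp.branch_table.query("significant and is_leaf")["node"]
    cells: list[str] = []
    for node in driving:
        in_cluster = cmp.assignment.cluster_of == node + 1
        cells.extend(cmp.assignment.cell_ids[in_cluster])
    if not cells:
        return
    table, best = match_to_atlas(cmp.normalized, cells, atlas,
                                 min_overlap=min_overlap)
    table.to_csv(outdir / "atlas_correlations.tsv", sep="\t")
    best.rename("best_match").to_csv(outdir / "atlas_best_match.tsv", sep="\t")
    summary["atlas_top_types"] = best.value_counts().head(5).index.tolist()


def write_multi_report(dm: DistanceMatrix, counts_table: pd.DataFrame,
                       outdir: str | Path) -> dict:
    """Write distance/p-value matrices, sample dendrogram and counts table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dm.distance.to_csv(outdir / "distance_matrix.tsv", sep="\t")
    dm.p_value.to_csv(outdir / "pvalue_matrix.tsv", sep="\t")
    newick, _ = sample_dendrogram(dm)
    (outdir / "sample_dendrogram.nwk").write_text(newick + "\n")
    counts_table.to_csv(outdir / "counts_per_cluster.tsv", sep="\t")
    summary = {"samples": dm.labels,
               "distance_matrix": "distance_matrix.tsv",
               "pvalue_matrix": "pvalue_matrix.tsv",
               "dendrogram": newick}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
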