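#!/usr/bin/env python
"""Optional validation against the published mass-cytometry mixture experiment.

Consumes a user-downloaded cells x markers table of T-cell development data
(continuous channel intensities with a ``population`` column labelling each
cell CD8 or CD4) and reruns the published scheme: N1 = 1000 CD8 cells,
N2 = a CD4/CD8 mixture at each proportion, 50 resampled runs, k = 10;
reports the fraction of significant runs per proportion (expected: <= 0.2%
false positives at proportion 0 and > 95% detection at 2%).

This requires an external download and therefore is not part of the test
suite; the synthetic analog in tests/test_acceptance.py covers the same
property at desk scale.

Usage:
  python scripts/validate_cytof.py --table cytof_cells.tsv \
      --proportions 0 0.02 0.05 0.1 --runs 50 --out cytof_validation.tsv
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from scunifrac import CountMatrix, RunConfig, compare_pair, sample_mixture, \
    summarize
from scunifrac.multisample import derive_seed


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--table", type=Path, required=True,
                        help="TSV: rows = cells, columns = markers plus a "
                             "'population' column with CD8/CD4 labels")
    parser.add_argument("--proportions", type=float, nargs="+",
                        default=[0.0, 0.02, 0.05, 0.1, 0.25, 0.5, 1.0])
    parser.add_argument("--runs", type=int, default=50)
    parser.add_argument("--n", type=int, default=1000)
    parser.add_argument("--k", type=int, default=10)
    parser.add_argument("--nperm", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("cytof_validation.tsv"))
    args = parser.parse_args()

    table = pd.read_csv(args.table, sep="\t", index_col=0)
    pops = table.pop("population").astype(str)
    values = table.T  # markers x cells
    pool_a = CountMatrix(values.loc[:, pops == "CD8"], "CD8", continuous=True)
    pool_b = CountMatrix(values.loc[:, pops == "CD4"], "CD4", continuous=True)
    cfg = RunConfig(k=args.k, n_permutations=args.nperm, no_normalize=True)

    rows = []
    for prop in args.proportions:
        for run in range(args.runs):
            s = derive_seed(args.seed, f"p{prop}", f"r{run}")
            s1, s2 = sample_mixture(pool_a, pool_b, args.n, args.n, prop, seed=s)
            res = compare_pair(s1, s2, cfg.replace(seed=s)).result
            rows.append({"proportion": prop, "k": args.k, "n2": args.n,
                         "run": run, "seed": s, "distance": res.distance,
                         "p_value": res.p_value,
                         "significant": res.p_value < 0.05})
    tidy = pd.DataFrame(rows)
    summary = summarize(tidy)
    summary.to_csv(args.out, sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
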