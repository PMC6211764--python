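"""Synthetic multi-population single-cell data and the sensitivity /
robustness experiments (mixture gradients, k sweeps, size imbalance).

The generative model: each population has a latent log-expression center —
a shared per-gene baseline plus an elevation of that population's marker
genes.  A cell's latent profile is its population center plus iid Gaussian
noise (``spread`` per gene); counts are Poisson draws with rates
proportional to exp(latent), scaled to a log-normally distributed library
size.  The ``separation`` parameter is the center offset per marker
dimension in units of the within-population spread, so ``separation=10``
yields the well-separated point clouds used throughout the test fixtures.
A CyTOF-like mode emits the latent matrix directly (continuous channels, no
count sampling), matching mass-cytometry-style inputs that bypass
normalization.

Mixture experiments follow the two-sample scheme: sample N1 is drawn purely
from pool A, while N2 mixes round(proportion * n2) pool-B cells (half-up
rounding) with pool-A cells, sampled without replacement within each draw
and independently across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import CountMatrix
from .multisample import derive_seed
from .unifrac import compare_pair


@dataclass
class PopulationSpec:
    """Parameters of the synthetic population mixture."""

    n_populations: int = 2
    n_genes: int = 500
    spread: float = 0.5          # latent per-gene SD within a population
    separation: float = 10.0     # center offset per marker dim, in spreads
    n_markers: int = 25          # marker genes per population
    baseline_mean: float = 1.0   # latent log-expression baseline
    baseline_sd: float = 0.5
    library_median: float = 2000.0
    library_sigma: float = 0.3   # log-normal sigma of library sizes
    cytof_like: bool = False     # emit latent values directly, no counts
    seed: int = 0                # fixes baseline and marker assignment

    def __post_init__(self) -> None:
        if self.n_markers * self.n_populations > self.n_genes:
            raise ValueError("not enough genes for disjoint marker sets")
        if self.spread < 0 or self.separation < 0:
            raise ValueError("spread and separation must be nonnegative")

    def centers(self) -> tuple[np.ndarray, list[np.ndarray]]:
        """(baseline, per-population marker index arrays); deterministic."""
        rng = np.random.default_rng(self.seed)
        baseline = self.baseline_mean + self.baseline_sd * rng.standard_normal(self.n_genes)
        markers = [np.arange(p * self.n_markers, (p + 1) * self.n_markers)
                   for p in range(self.n_populations)]
        return baseline, markers

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]


def generate_population_data(spec: PopulationSpec, n_cells: int, seed: int,
                             weights: list[float] | None = None,
                             sample_label: str = "sample") -> CountMatrix:
    """Draw ``n_cells`` cells; population memberships follow ``weights``
    (balanced by default).  Cell IDs carry their true population
    (``popP_cellC``) so downstream checks can recover the ground truth."""
    rng = np.random.default_rng(seed)
    P = spec.n_populations
    if weights is None:
        weights = [1.0 / P] * P
    w = np.asarray(weights, dtype=float)
    if len(w) != P or (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative, one per population")
    w = w / w.sum()
    if n_cells < int((w > 0).sum()):
        raise ValueError("n_cells smaller than number of populations drawn")
    membership = rng.choice(P, size=n_cells, p=w)

    baseline, markers = spec.centers()
    effect = spec.separation * spec.spread
    centers = np.tile(baseline, (P, 1))
    for p in range(P):
        centers[p, markers[p]] += effect
    latent = centers[membership] + spec.spread * rng.standard_normal(
        (n_cells, spec.n_genes))

    cell_ids = [f"pop{m}_cell{i}" for i, m in enumerate(membership)]
    if spec.cytof_like:
        values = latent.T
    else:
        rates = np.exp(latent)
        rates /= rates.sum(axis=1, keepdims=True)
        lib = rng.lognormal(math.log(spec.library_median), spec.library_sigma,
                            size=n_cells)
        values = rng.poisson(lib[:, None] * rates).T.astype(float)
    df = pd.DataFrame(values, index=spec.gene_ids(), columns=cell_ids)
    return CountMatrix(df, sample_label, continuous=spec.cytof_like)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sample_mixture(pool_a: CountMatrix, pool_b: CountMatrix, n1: int, n2: int,
                   proportion: float, seed: int,
                   labels: tuple[str, str] = ("N1", "N2")
                   ) -> tuple[CountMatrix, CountMatrix]:
    """Draw the two-sample mixture design.

    N1 = ``n1`` cells from pool A; N2 = round(proportion * n2) cells from
    pool B plus the remainder from pool A.  Sampling is without replacement
    within each draw.
    """
    if not 0 <= proportion <= 1:
        raise ValueError("proportion must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_b = _round_half_up(proportion * n2)
    n_a2 = n2 - n_b
    if n1 + n_a2 > pool_a.n_cells:
        raise ValueError("pool A too small for requested draw")
    if n_b > pool_b.n_cells:
        raise ValueError("pool B too small for requested draw")
    pick_a = rng.choice(pool_a.n_cells, size=n1 + n_a2, replace=False)
    n1_cells = pool_a.cell_ids[pick_a[:n1]]
    a2_cells = pool_a.cell_ids[pick_a[n1:]]
    b_cells = pool_b.cell_ids[rng.choice(pool_b.n_cells, size=n_b,
                                         replace=False)] if n_b else []
    cont = pool_a.continuous or pool_b.continuous
    s1 = CountMatrix(pool_a.values[list(n1_cells)].copy(), labels[0],
                     continuous=cont)
    v2 = pd.concat([pool_a.values[list(a2_cells)],
                    pool_b.values[list(b_cells)]], axis=1)
    # disambiguate: a cell may appear in both draws of N2's parent pools
    v2.columns = [f"{c}#{i}" for i, c in enumerate(v2.columns)]
    s2 = CountMatrix(v2.copy(), labels[1], continuous=cont)
    return s1, s2


@dataclass
class MixtureDesign:
    """Grid for the sensitivity / imbalance experiments."""

    proportions: list[float] = field(default_factory=lambda: [0.0, 0.02, 0.05, 0.1, 0.25, 0.5, 1.0])
    k_grid: list[int] = field(default_factory=lambda: [10])
    n1: int = 1000
    n2: int = 1000
    n2_grid: list[int] | None = None
    runs: int = 50
    pool_size: int = 4000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if any(not 0 <= p <= 1 for p in self.proportions):
            raise ValueError("proportions must lie in [0, 1]")


def _run_grid(spec: PopulationSpec, design: MixtureDesign, config: RunConfig,
              n2_values: list[int]) -> pd.DataFrame:
    pool_a = generate_population_data(spec, design.pool_size,
                                      derive_seed(design.seed, "poolA"),
                                      weights=[1.0, 0.0], sample_label="poolA")
    pool_b = generate_population_data(spec, design.pool_size,
                                      derive_seed(design.seed, "poolB"),
                                      weights=[0.0, 1.0], sample_label="poolB")
    rows = []
    for prop in design.proportions:
        for k in design.k_grid:
            for n2 in n2_values:
                for run in range(design.runs):
                    s = derive_seed(design.seed, f"p{prop}", f"k{k}",
                                    f"n{n2}", f"r{run}")
                    s1, s2 = sample_mixture(pool_a, pool_b, design.n1, n2,
                                            prop, seed=s)
                    cmp = compare_pair(s1, s2, config.replace(k=k, seed=s))
                    rows.append({
                        "proportion": prop, "k": k, "n2": n2, "run": run,
                        "seed": s, "distance": cmp.result.distance,
                        "p_value": cmp.result.p_value,
                        "significant": cmp.result.p_value < design.alpha})
    return pd.DataFrame(rows)


def summarize(tidy: pd.DataFrame) -> pd.DataFrame:
    """Per grid point: mean/quartile distance and fraction significant."""
    g = tidy.groupby(["proportion", "k", "n2"])
    out = g.agg(mean_distance=("distance", "mean"),
                q1_distance=("distance", lambda x: x.quantile(0.25)),
                q3_distance=("distance", lambda x: x.quantile(0.75)),
                fraction_significant=("significant", "mean"),
                runs=("run", "size"))
    return out.reset_index()


def run_sensitivity(spec: PopulationSpec, design: MixtureDesign,
                    config: RunConfig | None = None) -> pd.DataFrame:
    """Mixture-gradient experiment: D and p for every (proportion, k, run).

    The returned tidy table has one row per run; ``summarize`` collapses it
    to the mean-distance and fraction-significant curves.
    """
    config = config or RunConfig(no_normalize=spec.cytof_like)
    return _run_grid(spec, design, config, [design.n2])


def run_imbalance(spec: PopulationSpec, design: MixtureDesign,
                  config: RunConfig | None = None) -> pd.DataFrame:
    """Dataset-size imbalance experiment: sweep n2 with n1 fixed."""
    if not design.n2_grid:
        raise ValueError("design.n2_grid must be set for the imbalance sweep")
    config = config or RunConfig(no_normalize=spec.cytof_like)
    return _run_grid(spec, design, config, design.n2_grid)
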