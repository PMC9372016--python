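"""kNN batch-mixing acceptance test per cell type (kBET-style).

For one cell type, a k-nearest-neighbor graph is built on the cells'
log-normalized expression (Euclidean metric, self-inclusive
neighborhoods). On each of ``n_runs`` runs, 10% of the cells are sampled
and each sampled cell's neighborhood batch composition is compared to the
global batch proportions with a chi-squared goodness-of-fit test at
alpha = 0.05; the run's rejection rate is the fraction of sampled cells
rejecting. The reported acceptance rate is the mean over runs of
(1 - rejection rate); values above 0.75 are treated as well mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.neighbors import NearestNeighbors

from .containers import ExpressionMatrix

#: acceptance above this is considered well mixed
WELL_MIXED_THRESHOLD = 0.75


@dataclass
class BatchQCResult:
    cell_type: str
    acceptance_rate: float = np.nan
    n_runs: int = 0
    n_cells_tested: int = 0
    k: int = 0
    well_mixed: bool = False
    skipped: bool = False
    reason: str = ""


def default_k(n_cells: int) -> int:
    """Neighborhood size when not given: max(10, 25% of the cells),
    capped at the number of cells."""
    return min(n_cells, max(10, int(np.ceil(0.25 * n_cells))))


def _chi2_gof_p(observed: np.ndarray, expected: np.ndarray) -> float:
    """Goodness-of-fit p with (B-1) df; categories whose expected count is
    below 1 are merged into the smallest remaining ones. A single
    category (df 0) never rejects."""
    order = np.argsort(expected)
    observed, expected = observed[order].astype(float), expected[order].astype(float)
    while len(expected) > 1 and expected[0] < 1.0:
        expected[1] += expected[0]
        observed[1] += observed[0]
        observed, expected = observed[1:], expected[1:]
        order = np.argsort(expected)
        observed, expected = observed[order], expected[order]
    if len(expected) < 2:
        return 1.0
    stat = float(((observed - expected) ** 2 / expected).sum())
    return float(scipy.stats.chi2.sf(stat, df=len(expected) - 1))


def batch_mixing_test(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    cell_type: str,
    batch_col: str = "batch",
    k: int | None = None,
    n_runs: int = 100,
    subsample_fraction: float = 0.10,
    alpha: float = 0.05,
    min_cells: int = 15,
    seed: int = 0,
) -> BatchQCResult:
    """Batch-mixing acceptance test for one cell type.

    Cell types with fewer than ``min_cells`` cells across the batches are
    skipped with a reason; batches contributing no cells of the type
    simply do not appear in the comparison.
    """
    annot = annot.loc[list(expr.cell_ids)]
    cols = np.flatnonzero((annot["cell_type"] == cell_type).to_numpy())
    n = cols.size
    if n < min_cells:
        return BatchQCResult(
            cell_type, skipped=True, reason=f"{n} cells < min_cells={min_cells}"
        )
    batches = annot.iloc[cols][batch_col].to_numpy()
    levels, codes = np.unique(batches, return_inverse=True)
    global_prop = np.bincount(codes, minlength=len(levels)) / n

    k = k if k is not None else default_k(n)
    k = min(k, n)
    x = expr.dense(cell_cols=cols).T  # cells x genes
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(x)
    neighbor_idx = nn.kneighbors(x, return_distance=False)  # self-inclusive
    # neighborhood batch composition per cell
    neigh_counts = np.zeros((n, len(levels)), dtype=int)
    for b in range(len(levels)):
        neigh_counts[:, b] = (codes[neighbor_idx] == b).sum(axis=1)
    expected = global_prop * k

    rng = np.random.default_rng(seed)
    n_sample = max(1, int(np.ceil(subsample_fraction * n)))
    rejection = np.empty(n_runs)
    pcache: dict[int, float] = {}
    for run in range(n_runs):
        sample = rng.choice(n, size=n_sample, replace=False)
        rejected = 0
        for i in sample:
            p = pcache.get(i)
            if p is None:
                p = _chi2_gof_p(neigh_counts[i], expected)
                pcache[i] = p
            rejected += p < alpha
        rejection[run] = rejected / n_sample
    acceptance = float(np.mean(1.0 - rejection))
    return BatchQCResult(
        cell_type=cell_type,
        acceptance_rate=acceptance,
        n_runs=n_runs,
        n_cells_tested=n,
        k=k,
        well_mixed=acceptance > WELL_MIXED_THRESHOLD,
    )


def batch_mixing_report(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    batch_col: str = "batch",
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`batch_mixing_test` for every cell type; one row each."""
    annot = annot.loc[list(expr.cell_ids)]
    rows = []
    for i, t in enumerate(sorted(annot["cell_type"].unique())):
        res = batch_mixing_test(
            expr, annot, t, batch_col=batch_col, seed=seed + i, **kwargs
        )
        rows.append(vars(res))
    return pd.DataFrame(rows)
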