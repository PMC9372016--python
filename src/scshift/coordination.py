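"""Ligand-receptor cell-cell coordination via cluster-label permutation.

For every ordered cluster pair (A, B) and ligand-receptor pair, the
interaction score is the arithmetic mean of the ligand's mean
log-normalized expression in A and the receptor's in B. A pair is tested
only when the ligand is expressed (> 0) in strictly more than 10% of A's
cells and the receptor in more than 10% of B's cells. The null shuffles
all cluster labels jointly (cluster sizes preserved) and recomputes the
score; the add-one empirical p compares observed to null. Per-tile counts
of significant pairs are reported for ordered pairs and as a symmetrized
sum (tile(A,B) + tile(B,A)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from ._utils import ScshiftError
from .containers import ExpressionMatrix


@dataclass
class InteractionMatrix:
    """Significant ligand-receptor interaction counts between clusters."""

    ordered_counts: pd.DataFrame  # ligand cluster (rows) x receptor cluster (cols)
    symmetric_counts: pd.DataFrame
    detail: pd.DataFrame  # one row per gated (ligand, receptor, A, B) test
    n_permutations: int = 0
    alpha: float = 0.05


def lr_interaction_test(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    pairs: pd.DataFrame,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_expressed_fraction: float = 0.10,
    min_cells_per_type: int = 10,
) -> InteractionMatrix:
    """Permutation test of ligand-receptor co-expression between clusters.

    ``pairs`` needs columns ligand / receptor; pairs whose genes are not
    in the matrix are dropped with a warning. Clusters with fewer than
    ``min_cells_per_type`` cells are excluded.
    """
    if n_permutations < 100:
        raise ScshiftError("n_permutations must be at least 100")
    annot = annot.loc[list(expr.cell_ids)]
    labels = annot["cell_type"].to_numpy()
    clusters = [
        c
        for c, n in annot["cell_type"].value_counts().sort_index().items()
        if n >= min_cells_per_type
    ]
    if len(clusters) < 2:
        raise ScshiftError("lr_interaction_test needs at least 2 clusters")

    known = set(expr.gene_ids)
    usable = pairs[pairs["ligand"].isin(known) & pairs["receptor"].isin(known)]
    dropped = len(pairs) - len(usable)
    if dropped:
        warnings.warn(f"{dropped} ligand-receptor pairs not in the matrix, dropped", stacklevel=2)

    genes = sorted(set(usable["ligand"]) | set(usable["receptor"]))
    if not genes:
        return _empty_result(clusters, n_permutations, alpha)
    x = expr.dense(expr.gene_index(genes))  # genes x all cells
    gpos = {g: i for i, g in enumerate(genes)}

    member_cols = {c: np.flatnonzero(labels == c) for c in clusters}
    # cluster means / expressed fractions under the observed labels
    mean_obs = np.column_stack([x[:, member_cols[c]].mean(axis=1) for c in clusters])
    pct_obs = np.column_stack([(x[:, member_cols[c]] > 0).mean(axis=1) for c in clusters])
    cpos = {c: j for j, c in enumerate(clusters)}

    # gate: ligand expressed in >10% of A, receptor in >10% of B
    tests = []  # (ligand, receptor, A, B, observed score)
    for lig, rec in usable.itertuples(index=False):
        li, ri = gpos[lig], gpos[rec]
        for a in clusters:
            if pct_obs[li, cpos[a]] <= min_expressed_fraction:
                continue
            for b in clusters:
                if a == b or pct_obs[ri, cpos[b]] <= min_expressed_fraction:
                    continue
                score = 0.5 * (mean_obs[li, cpos[a]] + mean_obs[ri, cpos[b]])
                tests.append((lig, rec, a, b, score))
    if not tests:
        warnings.warn("no ligand-receptor pair passed the expression gate", stacklevel=2)
        return _empty_result(clusters, n_permutations, alpha)

    # averaging matrix: cell -> cluster mean weights (fixed positions; the
    # null permutes which cells occupy them)
    n_cells = x.shape[1]
    w = np.zeros((n_cells, len(clusters)))
    for c, cols in member_cols.items():
        w[cols, cpos[c]] = 1.0 / cols.size

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(tests), dtype=int)
    obs = np.array([t[4] for t in tests])
    li_arr = np.array([gpos[t[0]] for t in tests])
    ri_arr = np.array([gpos[t[1]] for t in tests])
    a_arr = np.array([cpos[t[2]] for t in tests])
    b_arr = np.array([cpos[t[3]] for t in tests])
    for _ in range(n_permutations):
        perm = rng.permutation(n_cells)
        means = x[:, perm] @ w  # genes x clusters under shuffled labels
        null_scores = 0.5 * (means[li_arr, a_arr] + means[ri_arr, b_arr])
        exceed += null_scores >= obs
    pvals = (1 + exceed) / (1 + n_permutations)

    detail = pd.DataFrame(
        {
            "ligand": [t[0] for t in tests],
            "receptor": [t[1] for t in tests],
            "cluster_a": [t[2] for t in tests],
            "cluster_b": [t[3] for t in tests],
            "score": obs,
            "p": pvals,
            "significant": pvals < alpha,
        }
    )
    ordered = pd.DataFrame(0, index=clusters, columns=clusters)
    for _, row in detail[detail["significant"]].iterrows():
        ordered.loc[row["cluster_a"], row["cluster_b"]] += 1
    symmetric = ordered + ordered.T
    return InteractionMatrix(ordered, symmetric, detail, n_permutations, alpha)


def _empty_result(clusters, n_permutations, alpha) -> InteractionMatrix:
    empty = pd.DataFrame(0, index=clusters, columns=clusters)
    detail = pd.DataFrame(
        columns=["ligand", "receptor", "cluster_a", "cluster_b", "score", "p", "significant"]
    )
    return InteractionMatrix(empty, empty.copy(), detail, n_permutations, alpha)
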