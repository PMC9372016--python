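"""Wilcoxon rank-sum differential expression with expression-fraction and
fold-change pre-filters, conserved-marker meta-testing, treatment-reversal
detection and Fisher's-exact pathway enrichment.

Genes enter the test only if expressed (value > 0) in at least
``min_expressed_fraction`` of the cells of one of the two groups and the
absolute log fold change is at least ``min_abs_log_fc``. Bonferroni uses
all genes in the dataset as the family (the convention of the software
family this procedure mirrors); correcting only over the filtered genes
would be anti-conservative, since the fold-change pre-filter selects
genes with randomly extreme effects. Fold change is
``ln[(mean(expm1 x1) + eps) / (mean(expm1 x2) + eps)]`` with eps = 1e-9,
i.e. the ratio of de-logged group means on the normalized scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from ._utils import ScshiftError
from .containers import ExpressionMatrix
from .stats import tippett_meta_p

_EPS = 1e-9
#: sample-size bound below which the exact rank-sum distribution is used
_EXACT_N = 25


@dataclass
class DEGParams:
    min_expressed_fraction: float = 0.10
    min_abs_log_fc: float = 0.25
    alpha_adjusted: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.min_expressed_fraction <= 1):
            raise ValueError("min_expressed_fraction must be in [0, 1]")
        if not (0 < self.alpha_adjusted < 1):
            raise ValueError("alpha_adjusted must be in (0, 1)")


def log_fold_change(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Natural-log ratio of de-logged group means (rows = genes)."""
    m1 = np.expm1(x1).mean(axis=1)
    m2 = np.expm1(x2).mean(axis=1)
    return np.log((m1 + _EPS) / (m2 + _EPS))


def rank_sum_p(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per gene row.

    Exact enumeration when both groups have <= 25 cells and the gene has
    no cross-group ties; otherwise the normal approximation with tie and
    continuity correction.
    """
    x1 = np.atleast_2d(x1)
    x2 = np.atleast_2d(x2)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 <= _EXACT_N and n2 <= _EXACT_N:
        p = np.empty(x1.shape[0])
        for i in range(x1.shape[0]):
            pooled = np.concatenate([x1[i], x2[i]])
            method = "exact" if len(np.unique(pooled)) == len(pooled) else "asymptotic"
            p[i] = scipy.stats.mannwhitneyu(
                x1[i], x2[i], alternative="two-sided", method=method
            ).pvalue
        return p
    res = scipy.stats.mannwhitneyu(
        x1, x2, alternative="two-sided", method="asymptotic", axis=1
    )
    return np.atleast_1d(res.pvalue)


def wilcoxon_de(
    expr: ExpressionMatrix,
    cells_group1,
    cells_group2,
    params: DEGParams | None = None,
) -> pd.DataFrame:
    """Differential expression between two disjoint cell groups.

    ``cells_group1`` / ``cells_group2`` are cell ids or integer column
    indices. Returns one row per gene passing the pre-filters, with
    log_fc (group1 over group2), expressed fractions, raw and
    Bonferroni-adjusted p, sorted by raw p.
    """
    params = params or DEGParams()
    idx1 = _as_cell_index(expr, cells_group1)
    idx2 = _as_cell_index(expr, cells_group2)
    if np.intersect1d(idx1, idx2).size:
        raise ScshiftError("the two groups overlap")
    if idx1.size == 0 or idx2.size == 0:
        raise ScshiftError("both groups must be nonempty")

    x1 = expr.dense(cell_cols=idx1)
    x2 = expr.dense(cell_cols=idx2)
    pct1 = (x1 > 0).mean(axis=1)
    pct2 = (x2 > 0).mean(axis=1)
    lfc = log_fold_change(x1, x2)
    tested = (np.maximum(pct1, pct2) >= params.min_expressed_fraction) & (
        np.abs(lfc) >= params.min_abs_log_fc
    )
    out = pd.DataFrame(
        {
            "gene": expr.gene_ids[tested],
            "log_fc": lfc[tested],
            "pct_group1": pct1[tested],
            "pct_group2": pct2[tested],
        }
    )
    if len(out) == 0:
        out["p_raw"] = out["p_adjusted"] = out["direction"] = []
        return out
    p_raw = rank_sum_p(x1[tested], x2[tested])
    out["p_raw"] = p_raw
    out["p_adjusted"] = np.minimum(p_raw * expr.n_genes, 1.0)
    out["direction"] = np.sign(out["log_fc"]).astype(int)
    return out.sort_values("p_raw", kind="stable").reset_index(drop=True)


def _as_cell_index(expr: ExpressionMatrix, cells) -> np.ndarray:
    arr = np.asarray(cells)
    if arr.dtype.kind in "iu":
        return arr.astype(int)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    return expr.cell_index(arr)


def conserved_markers(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    cluster: str,
    params: DEGParams | None = None,
    strata_cols: tuple[str, ...] = ("timepoint", "condition"),
    min_cells: int = 3,
) -> pd.DataFrame:
    """Markers of ``cluster`` conserved across timepoint x condition strata.

    Within each stratum the cluster's cells are tested against all other
    cells with :func:`wilcoxon_de`; genes surviving the pre-filters in
    every usable stratum get a Tippett minimum-p meta p-value across
    strata, Bonferroni-corrected over the meta-tested genes. Only genes
    with adjusted meta p below alpha and a consistent fold-change
    direction across strata are returned.
    """
    import warnings

    params = params or DEGParams()
    annot = annot.loc[list(expr.cell_ids)]
    usable: dict[tuple, pd.DataFrame] = {}
    for key, sub in annot.groupby(list(strata_cols), observed=True, sort=True):
        in_cluster = sub.index[sub["cell_type"] == cluster]
        out_cluster = sub.index[sub["cell_type"] != cluster]
        if len(in_cluster) < min_cells or len(out_cluster) < min_cells:
            warnings.warn(
                f"stratum {key}: cluster {cluster!r} too small, dropped", stacklevel=2
            )
            continue
        usable[key] = wilcoxon_de(expr, list(in_cluster), list(out_cluster), params)
    if len(usable) < 2:
        raise ScshiftError(
            f"conserved_markers needs >=2 usable strata, found {len(usable)}"
        )

    common = set.intersection(*(set(t["gene"]) for t in usable.values()))
    rows = []
    k = len(usable)
    for gene in sorted(common):
        recs = [t.loc[t["gene"] == gene].iloc[0] for t in usable.values()]
        signs = {int(r["direction"]) for r in recs}
        meta = tippett_meta_p([float(r["p_raw"]) for r in recs], k=k)
        rows.append(
            {
                "gene": gene,
                "meta_p": meta,
                "min_log_fc": min(float(r["log_fc"]) for r in recs),
                "max_log_fc": max(float(r["log_fc"]) for r in recs),
                "consistent": len(signs) == 1,
                "direction": signs.pop() if len(signs) == 1 else 0,
            }
        )
    table = pd.DataFrame(rows)
    if len(table) == 0:
        return table
    table["meta_p_adjusted"] = np.minimum(table["meta_p"] * expr.n_genes, 1.0)
    keep = table["consistent"] & (table["meta_p_adjusted"] < params.alpha_adjusted)
    return (
        table[keep]
        .sort_values("meta_p_adjusted", kind="stable")
        .reset_index(drop=True)
    )


def reversed_genes(
    deg_perturbed_vs_control: pd.DataFrame,
    deg_treated_vs_perturbed: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes significantly changed by the perturbation and significantly
    moved the opposite way by the treatment.

    Both inputs are :func:`wilcoxon_de` tables from the same cell type; a
    gene is reversed when its adjusted p is below ``alpha`` in both and
    the fold-change signs are opposite.
    """
    a = deg_perturbed_vs_control.set_index("gene")
    b = deg_treated_vs_perturbed.set_index("gene")
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    mask = (
        (a["p_adjusted"] < alpha)
        & (b["p_adjusted"] < alpha)
        & (np.sign(a["log_fc"]) * np.sign(b["log_fc"]) < 0)
    )
    out = pd.DataFrame(
        {
            "gene": shared[mask],
            "log_fc_perturbation": a.loc[mask, "log_fc"].to_numpy(),
            "p_adjusted_perturbation": a.loc[mask, "p_adjusted"].to_numpy(),
            "log_fc_treatment": b.loc[mask, "log_fc"].to_numpy(),
            "p_adjusted_treatment": b.loc[mask, "p_adjusted"].to_numpy(),
        }
    )
    return out.sort_values("gene", kind="stable").reset_index(drop=True)


def fisher_enrichment(
    query_genes, gene_sets: dict, universe
) -> pd.DataFrame:
    """One-sided Fisher's exact enrichment of ``query_genes`` in each gene
    set, Benjamini-Hochberg corrected across the sets tested.

    Query and sets are intersected with ``universe`` first; the 2x2 table
    is (overlap, query - overlap, set - overlap, rest of universe).
    """
    universe = set(universe)
    if not universe:
        raise ScshiftError("empty gene universe")
    query = set(query_genes) & universe
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        if not members:
            continue
        overlap = len(query & members)
        table = [
            [overlap, len(query) - overlap],
            [len(members) - overlap, len(universe) - len(query) - len(members) + overlap],
        ]
        _, p = scipy.stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "gene_set": name,
                "overlap": overlap,
                "set_size": len(members),
                "query_size": len(query),
                "universe_size": len(universe),
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p_raw"], method="fdr_bh")[1]
        out = out.sort_values("p_raw", kind="stable").reset_index(drop=True)
    return out
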