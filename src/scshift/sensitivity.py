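"""Per-cell-type perturbation-sensitivity metrics and the consensus rank.

Three complementary resampling metrics quantify how far a cell type's
transcriptome moved between two conditions:

* Euclidean shift — distance between the per-condition mean z-score
  vectors ("representative cells") over the top-N most highly expressed
  genes, against a condition-label permutation null (empirical add-one
  p, log2 fold change of the observed distance over the null mean).
* SVM shift — median held-out accuracy of a linear soft-margin
  classifier predicting the condition label over repeated stratified
  70/30 splits; separable transcriptomes classify well, unperturbed
  ones sit at chance.
* Subsample-DEG count — number of genes with a significant Tippett
  meta p-value over repeated equal-size (default 100-cell) subsampled
  Wilcoxon DE runs, equalizing statistical power across cell types.

Within each tissue x timepoint stratum every metric ranks the cell types
(rank 1 = most perturbed, average ranks on ties) and the consensus is the
equal-weight arithmetic mean of the three ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.model_selection import (
    RepeatedStratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.svm import SVC

from ._utils import ScshiftError, stable_seed
from .containers import ExpressionMatrix
from .stats import empirical_p, tippett_meta_p

__all__ = [
    "ShiftParams",
    "EDResult",
    "SVMResult",
    "SubsampleDEGResult",
    "top_expressed_genes",
    "zscore_genes",
    "euclidean_shift",
    "svm_shift",
    "subsample_deg_count",
    "tippett_meta_p",
    "consensus_rank",
    "consensus_from_ranks",
    "sensitivity_report",
]


@dataclass
class ShiftParams:
    """Knobs of the three shift metrics (defaults follow the protocol the
    package implements: top 1000 genes, 1000 resamples, 70/30 splits with
    10-fold x 3-repeat CV, 100-cell subsamples, >=10 cells per group)."""

    top_n_genes: int = 1000
    n_permutations: int = 1000
    n_bootstraps: int = 1000
    train_fraction: float = 0.7
    cv_folds: int = 10
    cv_repeats: int = 3
    subsample_n: int = 100
    min_cells_per_group: int = 10
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        for name in ("top_n_genes", "n_permutations", "n_bootstraps", "subsample_n", "min_cells_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class EDResult:
    cell_type: str
    observed_distance: float = np.nan
    null_mean: float = np.nan
    null_sd: float = np.nan
    log_fc_vs_null: float = np.nan
    p_empirical: float = np.nan
    p_adjusted: float = np.nan
    skipped: bool = False
    reason: str = ""


@dataclass
class SVMResult:
    cell_type: str
    accuracies: np.ndarray = field(default_factory=lambda: np.array([]))
    median_accuracy: float = np.nan
    mean_cv_accuracy: float = np.nan
    skipped: bool = False
    reason: str = ""


@dataclass
class SubsampleDEGResult:
    cell_type: str
    meta_p: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    n_significant: int = 0
    skipped: bool = False
    reason: str = ""


def top_expressed_genes(expr: ExpressionMatrix, cells, n: int) -> list[str]:
    """The ``n`` most highly expressed genes over the given cells.

    Sorted by mean log-normalized expression (conditions pooled),
    descending; ties broken lexicographically by gene id. Returns all
    genes when ``n`` exceeds the gene count.
    """
    idx = _cell_cols(expr, cells)
    if idx.size == 0:
        raise ScshiftError("top_expressed_genes needs a nonempty cell set")
    means = np.asarray(expr.values[:, idx].mean(axis=1)).ravel()
    order = (
        pd.DataFrame({"gene": expr.gene_ids, "mean": means})
        .sort_values(["mean", "gene"], ascending=[False, True], kind="stable")
    )
    return order["gene"].head(n).tolist()


def zscore_genes(x: np.ndarray) -> np.ndarray:
    """Row-wise z-scores (genes x cells) with sample (n-1) standard
    deviation; zero-variance genes map to all-zero rows."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ScshiftError("z-scoring needs at least two cells")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    safe = np.where(sd > 0, sd, 1.0)
    z = (x - mean) / safe
    z[(sd == 0).ravel(), :] = 0.0
    return z


def _cell_cols(expr: ExpressionMatrix, cells) -> np.ndarray:
    arr = np.asarray(cells)
    if arr.dtype.kind in "iu":
        return arr.astype(int)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    return expr.cell_index(arr)


def _group_columns(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    cell_type: str,
    conditions: tuple[str, str],
) -> tuple[np.ndarray, np.ndarray]:
    annot = annot.loc[list(expr.cell_ids)]
    mask_type = (annot["cell_type"] == cell_type).to_numpy()
    g1 = np.flatnonzero(mask_type & (annot["condition"] == conditions[0]).to_numpy())
    g2 = np.flatnonzero(mask_type & (annot["condition"] == conditions[1]).to_numpy())
    return g1, g2


def euclidean_shift(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    cell_type: str,
    params: ShiftParams | None = None,
    conditions: tuple[str, str] = ("control", "perturbed"),
    rng: np.random.Generator | None = None,
) -> EDResult:
    """Permutation test of the between-condition representative-cell
    distance for one cell type.

    Gene selection and z-scoring are computed once on the pooled cells;
    the null permutes condition labels with group sizes preserved, which
    keeps the null exchangeable with the observed statistic.
    """
    params = params or ShiftParams()
    rng = rng or np.random.default_rng(stable_seed(params.seed, "ed", cell_type))
    g1, g2 = _group_columns(expr, annot, cell_type, conditions)
    n1, n2 = g1.size, g2.size
    if min(n1, n2) < params.min_cells_per_group:
        return EDResult(
            cell_type,
            skipped=True,
            reason=f"group sizes {n1}/{n2} below min_cells_per_group={params.min_cells_per_group}",
        )
    pooled = np.concatenate([g1, g2])
    genes = top_expressed_genes(expr, pooled, params.top_n_genes)
    z = zscore_genes(expr.dense(expr.gene_index(genes), pooled))

    base = np.concatenate([np.full(n1, 1.0 / n1), np.full(n2, -1.0 / n2)])
    observed = float(np.linalg.norm(z @ base))
    weights = rng.permuted(
        np.tile(base, (params.n_permutations, 1)), axis=1
    ).T  # cells x permutations
    null = np.linalg.norm(z @ weights, axis=0)

    null_mean = float(null.mean())
    if observed > 0 and null_mean > 0:
        log_fc = float(np.log2(observed / null_mean))
    elif observed == 0 and null_mean == 0:
        log_fc = 0.0
    else:
        log_fc = float(np.inf if observed > null_mean else -np.inf)
    return EDResult(
        cell_type=cell_type,
        observed_distance=observed,
        null_mean=null_mean,
        null_sd=float(null.std(ddof=1)) if null.size > 1 else 0.0,
        log_fc_vs_null=log_fc,
        p_empirical=empirical_p(null, observed),
    )


def svm_shift(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    cell_type: str,
    params: ShiftParams | None = None,
    conditions: tuple[str, str] = ("control", "perturbed"),
    rng: np.random.Generator | None = None,
) -> SVMResult:
    """Bootstrap held-out accuracy of a linear SVM (C = 1) predicting the
    condition label from the top-N z-scored genes.

    Each bootstrap draws a stratified 70/30 split, optionally runs
    repeated stratified k-fold CV on the training portion (protocol
    fidelity only — nothing is tuned), fits on the training cells and
    records accuracy on the untouched held-out 30%.
    """
    params = params or ShiftParams()
    rng = rng or np.random.default_rng(stable_seed(params.seed, "svm", cell_type))
    g1, g2 = _group_columns(expr, annot, cell_type, conditions)
    if min(g1.size, g2.size) < params.min_cells_per_group:
        return SVMResult(
            cell_type,
            skipped=True,
            reason=f"group sizes {g1.size}/{g2.size} below min_cells_per_group={params.min_cells_per_group}",
        )
    pooled = np.concatenate([g1, g2])
    genes = top_expressed_genes(expr, pooled, params.top_n_genes)
    x = zscore_genes(expr.dense(expr.gene_index(genes), pooled)).T  # cells x genes
    y = np.concatenate([np.zeros(g1.size, int), np.ones(g2.size, int)])

    accuracies = np.empty(params.n_bootstraps)
    cv_scores: list[float] = []
    for b in range(params.n_bootstraps):
        state = int(rng.integers(2**31))
        x_tr, x_te, y_tr, y_te = train_test_split(
            x, y, train_size=params.train_fraction, stratify=y, random_state=state
        )
        clf = SVC(kernel="linear", C=1.0)
        min_class = int(np.bincount(y_tr).min())
        if params.cv_repeats > 0 and params.cv_folds > 1 and min_class >= params.cv_folds:
            cv = RepeatedStratifiedKFold(
                n_splits=params.cv_folds,
                n_repeats=params.cv_repeats,
                random_state=state,
            )
            cv_scores.append(float(cross_val_score(clf, x_tr, y_tr, cv=cv).mean()))
        clf.fit(x_tr, y_tr)
        accuracies[b] = clf.score(x_te, y_te)
    return SVMResult(
        cell_type=cell_type,
        accuracies=accuracies,
        median_accuracy=float(np.median(accuracies)),
        mean_cv_accuracy=float(np.mean(cv_scores)) if cv_scores else np.nan,
    )


def subsample_deg_count(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    cell_type: str,
    params: ShiftParams | None = None,
    conditions: tuple[str, str] = ("control", "perturbed"),
    deg_params=None,
    rng: np.random.Generator | None = None,
) -> SubsampleDEGResult:
    """Stable DEG count from repeated equal-size subsampled DE runs.

    Conditions with more than ``subsample_n`` cells are subsampled to
    ``subsample_n`` (smaller groups are used whole) and the Wilcoxon DE
    test with its pre-filters is run; genes filtered out in a replicate
    contribute an adjusted p of 1. Per gene the replicate-wise Bonferroni
    p's are combined with Tippett's minimum-p rule (k = n_permutations)
    and genes with meta p below alpha are counted.
    """
    from .differential import DEGParams, wilcoxon_de

    params = params or ShiftParams()
    deg_params = deg_params or DEGParams()
    rng = rng or np.random.default_rng(stable_seed(params.seed, "deg", cell_type))
    g1, g2 = _group_columns(expr, annot, cell_type, conditions)
    if min(g1.size, g2.size) < params.min_cells_per_group:
        return SubsampleDEGResult(
            cell_type,
            skipped=True,
            reason=f"group sizes {g1.size}/{g2.size} below min_cells_per_group={params.min_cells_per_group}",
        )
    gene_ids = expr.gene_ids
    pos = {g: i for i, g in enumerate(gene_ids)}
    min_adj_p = np.ones(len(gene_ids))
    no_subsampling = g1.size <= params.subsample_n and g2.size <= params.subsample_n
    n_reps = 1 if no_subsampling else params.n_permutations
    for _ in range(n_reps):
        s1 = g1 if g1.size <= params.subsample_n else rng.choice(g1, params.subsample_n, replace=False)
        s2 = g2 if g2.size <= params.subsample_n else rng.choice(g2, params.subsample_n, replace=False)
        table = wilcoxon_de(expr, s1, s2, deg_params)
        if len(table):
            idx = np.fromiter((pos[g] for g in table["gene"]), int, len(table))
            np.minimum.at(min_adj_p, idx, table["p_adjusted"].to_numpy())
    # Tippett across the permutation family (identical replicates when no
    # subsampling happened, so k is still the nominal family size)
    with np.errstate(divide="ignore"):
        meta = -np.expm1(params.n_permutations * np.log1p(-np.minimum(min_adj_p, 1.0)))
    meta = np.where(min_adj_p >= 1.0, 1.0, meta)
    series = pd.Series(meta, index=gene_ids, name="meta_p")
    return SubsampleDEGResult(
        cell_type=cell_type,
        meta_p=series,
        n_significant=int((series < params.alpha).sum()),
    )


def _average_rank_desc(values: Sequence[float]) -> np.ndarray:
    """Rank 1 = largest value; ties share the average rank."""
    return scipy.stats.rankdata([-v for v in values], method="average")


def consensus_rank(
    ed: Mapping[str, float],
    svm: Mapping[str, float],
    deg: Mapping[str, float],
) -> pd.DataFrame:
    """Equal-weight consensus of the three metric rankings.

    Inputs map cell type -> ranking statistic (Euclidean log2 FC vs
    null, median SVM accuracy, subsample-DEG count). All three must
    cover the same cell types. Returns a table sorted by avg_rank.
    """
    keys = sorted(ed)
    for name, other in (("svm", svm), ("deg", deg)):
        if set(other) != set(ed):
            missing = sorted(set(ed) ^ set(other))
            raise ScshiftError(f"cell-type sets differ between ed and {name}: {missing}")
    ed_v = [float(ed[k]) for k in keys]
    svm_v = [float(svm[k]) for k in keys]
    deg_v = [float(deg[k]) for k in keys]
    out = pd.DataFrame(
        {
            "cell_type": keys,
            "ed_statistic": ed_v,
            "svm_statistic": svm_v,
            "deg_statistic": deg_v,
            "ed_rank": _average_rank_desc(ed_v),
            "svm_rank": _average_rank_desc(svm_v),
            "deg_rank": _average_rank_desc(deg_v),
        }
    )
    out["avg_rank"] = out[["ed_rank", "svm_rank", "deg_rank"]].mean(axis=1)
    return out.sort_values(["avg_rank", "cell_type"], kind="stable").reset_index(drop=True)


def consensus_from_ranks(ranks: pd.DataFrame) -> pd.DataFrame:
    """Average precomputed per-method ranks (columns ed_rank, svm_rank,
    deg_rank) into avg_rank, sorted ascending."""
    out = ranks.copy()
    out["avg_rank"] = out[["ed_rank", "svm_rank", "deg_rank"]].mean(axis=1)
    return out.sort_values("avg_rank", kind="stable").reset_index(drop=True)


def sensitivity_report(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    params: ShiftParams | None = None,
    stratify: tuple[str, ...] = ("tissue", "timepoint"),
    conditions: tuple[str, str] = ("control", "perturbed"),
    deg_params=None,
) -> tuple[pd.DataFrame, dict]:
    """Run all three metrics per cell type within each stratum and build
    the consensus table.

    Cell types with fewer than ``min_cells_per_group`` cells in either
    condition are skipped and excluded from all three rankings. Euclidean
    empirical p-values are Bonferroni-corrected across the cell types
    tested within the same stratum. Returns (report, details) where
    details maps stratum -> per-method result objects.
    """
    params = params or ShiftParams()
    annot = annot.loc[list(expr.cell_ids)]
    reports, details = [], {}
    for stratum, sub in annot.groupby(list(stratify), observed=True, sort=True):
        stratum = stratum if isinstance(stratum, tuple) else (stratum,)
        eligible, skipped = [], {}
        for t in sorted(sub["cell_type"].unique()):
            g1, g2 = _group_columns(expr, sub, t, conditions)
            if min(g1.size, g2.size) >= params.min_cells_per_group:
                eligible.append(t)
            else:
                skipped[t] = f"group sizes {g1.size}/{g2.size} too small"
        ed_res, svm_res, deg_res = {}, {}, {}
        for t in eligible:
            seed_key = (params.seed, *stratum, t)
            ed_res[t] = euclidean_shift(
                expr, sub, t, params, conditions,
                rng=np.random.default_rng(stable_seed(*seed_key, "ed")),
            )
            svm_res[t] = svm_shift(
                expr, sub, t, params, conditions,
                rng=np.random.default_rng(stable_seed(*seed_key, "svm")),
            )
            deg_res[t] = subsample_deg_count(
                expr, sub, t, params, conditions, deg_params,
                rng=np.random.default_rng(stable_seed(*seed_key, "deg")),
            )
        k = len(eligible)
        for t in eligible:  # Bonferroni family = cell types in this stratum
            ed_res[t].p_adjusted = min(1.0, ed_res[t].p_empirical * k)
        if not eligible:
            details[stratum] = {"skipped": skipped}
            continue
        table = consensus_rank(
            {t: ed_res[t].log_fc_vs_null for t in eligible},
            {t: svm_res[t].median_accuracy for t in eligible},
            {t: deg_res[t].n_significant for t in eligible},
        )
        for col, val in zip(stratify, stratum):
            table.insert(0, col, val)
        table["ed_p_adjusted"] = [ed_res[t].p_adjusted for t in table["cell_type"]]
        reports.append(table)
        details[stratum] = {"ed": ed_res, "svm": svm_res, "deg": deg_res, "skipped": skipped}
    report = (
        pd.concat(reports, ignore_index=True)
        if reports
        else pd.DataFrame(columns=[*stratify, "cell_type", "avg_rank"])
    )
    return report, details
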