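"""Reading/writing standard formats, cell quality filtering, log-normalization.

Input dialects: MatrixMarket triplet (matrix.mtx + features.tsv +
barcodes.tsv, 10x-style, 1-based on disk per the MatrixMarket standard,
0-based in memory), dense TSV for toy matrices, annotation TSV, GMT gene
sets and two-column ligand-receptor TSV.

Quality filter: a cell is kept when it has at least ``min_genes`` detected
genes (count > 0) and a mitochondrial UMI fraction strictly below
``max_mito_fraction`` (a cell at exactly the maximum is removed).
Normalization scales each cell to ``scale_factor`` total, then log(1 + x),
natural log.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._utils import EmptyAfterQCError, FormatError
from .containers import CountMatrix, ExpressionMatrix, validate_annotation


@dataclass
class QCParams:
    """Cell-quality thresholds.

    min_genes: minimum number of detected genes (count > 0) per cell.
    max_mito_fraction: upper bound on mitochondrial UMI fraction; cells
        with fraction >= this value are removed.
    mito_gene_prefix: genes whose id starts with this prefix are counted
        as mitochondrial (mouse convention "mt-"); an explicit
        ``mito_genes`` list overrides the prefix.
    """

    min_genes: int = 200
    max_mito_fraction: float = 0.15
    mito_gene_prefix: str = "mt-"
    mito_genes: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.max_mito_fraction <= 1):
            raise ValueError("max_mito_fraction must be in (0, 1]")
        if self.min_genes < 1:
            raise ValueError("min_genes must be positive")

    def mito_mask(self, gene_ids: np.ndarray) -> np.ndarray:
        if self.mito_genes is not None:
            wanted = set(self.mito_genes)
            return np.array([g in wanted for g in gene_ids])
        return np.array([str(g).startswith(self.mito_gene_prefix) for g in gene_ids])


def _read_single_column(path: str) -> list[str]:
    # features.tsv may have extra columns (id, symbol, type); first column wins
    rows = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return rows.iloc[:, 0].tolist()


def read_count_matrix(mtx_path: str, features_path: str, barcodes_path: str) -> CountMatrix:
    """Read a MatrixMarket triplet into a :class:`CountMatrix`.

    File order of genes and cells is preserved. Raises
    :class:`FormatError` naming the offending file on a dimension
    mismatch, and on non-integer or negative entries.
    """
    try:
        mat = scipy.io.mmread(mtx_path)
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"cannot parse MatrixMarket file {mtx_path}: {exc}") from exc
    genes = _read_single_column(features_path)
    cells = _read_single_column(barcodes_path)
    n_genes, n_cells = mat.shape
    if len(genes) != n_genes:
        raise FormatError(
            f"{features_path}: {len(genes)} rows but matrix declares {n_genes} genes"
        )
    if len(cells) != n_cells:
        raise FormatError(
            f"{barcodes_path}: {len(cells)} rows but matrix declares {n_cells} cells"
        )
    if not np.issubdtype(mat.dtype, np.integer):
        data = mat.data if sp.issparse(mat) else np.asarray(mat)
        if not np.array_equal(data, np.round(data)):
            raise FormatError(f"{mtx_path}: matrix contains non-integer entries")
        mat = mat.astype(np.int64)
    return CountMatrix(sp.csr_matrix(mat), np.array(genes, dtype=object), np.array(cells, dtype=object))


def write_count_matrix(counts: CountMatrix, out_dir: str) -> dict[str, str]:
    """Write the MTX triplet (matrix.mtx, features.tsv, barcodes.tsv)."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "mtx": os.path.join(out_dir, "matrix.mtx"),
        "features": os.path.join(out_dir, "features.tsv"),
        "barcodes": os.path.join(out_dir, "barcodes.tsv"),
    }
    scipy.io.mmwrite(paths["mtx"], counts.values.tocoo(), field="integer")
    pd.Series(counts.gene_ids).to_csv(paths["features"], sep="\t", header=False, index=False)
    pd.Series(counts.cell_ids).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    return paths


def read_dense_counts(path: str) -> CountMatrix:
    """Read a dense TSV (rows = genes, header = cell ids) as counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.array_equal(values, np.round(values)):
        raise FormatError(f"{path}: dense count table contains non-integer entries")
    return CountMatrix(
        sp.csr_matrix(values.astype(np.int64)),
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
    )


def write_dense_counts(counts: CountMatrix, path: str) -> None:
    counts.to_dense_frame().to_csv(path, sep="\t")


def read_annotation(path: str, cell_ids=None) -> pd.DataFrame:
    """Read and validate a per-cell annotation TSV (needs a cell_id column)."""
    annot = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in annot.columns:
        raise FormatError(f"{path}: annotation table needs a cell_id column")
    return validate_annotation(annot, cell_ids=cell_ids)


def write_annotation(annot: pd.DataFrame, path: str) -> None:
    annot.rename_axis("cell_id").to_csv(path, sep="\t")


def read_gmt(path: str) -> dict[str, list[str]]:
    """Parse a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{line_no}: GMT rows need name, description and >=1 gene")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def read_lr_pairs(path: str) -> pd.DataFrame:
    """Read a two-column ligand/receptor TSV (header: ligand, receptor)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "ligand" not in cols or "receptor" not in cols:
        raise FormatError(f"{path}: ligand-receptor table needs 'ligand' and 'receptor' columns")
    df.columns = cols
    return df[["ligand", "receptor"]]


def bundled_lr_pairs() -> pd.DataFrame:
    """The small ligand-receptor table shipped with the package."""
    path = os.path.join(os.path.dirname(__file__), "data", "lr_pairs_toy.tsv")
    return read_lr_pairs(path)


def cell_qc_table(counts: CountMatrix, qc: QCParams) -> pd.DataFrame:
    """Per-cell QC metrics and pass/fail verdicts (no filtering applied)."""
    csc = counts.values.tocsc()
    genes_detected = np.diff(csc.indptr)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    mito = qc.mito_mask(counts.gene_ids)
    mito_totals = (
        np.asarray(csc[mito, :].sum(axis=0)).ravel() if mito.any() else np.zeros_like(totals)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)
    low_genes = genes_detected < qc.min_genes
    high_mito = mito_fraction >= qc.max_mito_fraction
    reason = np.select(
        [low_genes & high_mito, low_genes, high_mito],
        ["low_genes;high_mito", "low_genes", "high_mito"],
        default="pass",
    )
    return pd.DataFrame(
        {
            "genes_detected": genes_detected,
            "total_umis": totals,
            "mito_fraction": mito_fraction,
            "passed": ~(low_genes | high_mito),
            "reason": reason,
        },
        index=pd.Index(counts.cell_ids, name="cell_id"),
    )


def filter_cells(counts: CountMatrix, qc: QCParams | None = None) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply the cell-quality filter; returns (filtered counts, QC table)."""
    qc = qc or QCParams()
    table = cell_qc_table(counts, qc)
    keep = table["passed"].to_numpy()
    if not keep.any():
        raise EmptyAfterQCError("no cells pass QC (empty after QC)")
    return counts.subset_cells(keep), table


def normalize(counts: CountMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """Log-normalize: per-cell scaling to ``scale_factor`` total then ln(1+x).

    Every cell must have nonzero total UMIs; run :func:`filter_cells`
    first if empty cells may be present.
    """
    csc = counts.values.tocsc().astype(np.float64)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValueError(
            "cells with zero total UMIs cannot be normalized; run filter_cells first"
        )
    per_entry_total = np.repeat(totals, np.diff(csc.indptr))
    csc.data = np.log1p(csc.data * (scale_factor / per_entry_total))
    return ExpressionMatrix(
        csc.tocsr(), counts.gene_ids.copy(), counts.cell_ids.copy(), scale_factor
    )
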