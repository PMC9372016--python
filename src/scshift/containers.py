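"""In-memory containers for UMI count and log-normalized expression matrices.

Matrices are stored genes x cells (rows = genes, columns = cells) as
scipy sparse CSR, mirroring the digital-gene-expression convention of
droplet scRNA-seq pipelines. Cell metadata travels separately as a
pandas DataFrame indexed by cell id (see :func:`validate_annotation`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import FormatError

#: Allowed values of the per-cell ``condition`` column.
CONDITIONS = ("control", "perturbed", "treated")

#: Columns an annotation table must provide.
REQUIRED_ANNOTATION_COLUMNS = ("sample_id", "condition", "cell_type")


def _check_ids(ids: np.ndarray, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        raise FormatError(f"{what} are not unique")
    return ids


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of nonnegative integer UMI counts."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = _check_ids(self.gene_ids, "gene ids")
        self.cell_ids = _check_ids(self.cell_ids, "cell ids")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes / {len(self.cell_ids)} cells"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            data = self.values.data
            if not np.array_equal(data, np.round(data)):
                raise FormatError("count matrix contains non-integer entries")
            self.values = self.values.astype(np.int64)
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("count matrix contains negative entries")
        self.values.eliminate_zeros()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.values[:, idx].tocsr(), self.gene_ids, self.cell_ids[idx]
        )

    def to_dense_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.toarray(), index=self.gene_ids, columns=self.cell_ids
        )


@dataclass
class ExpressionMatrix:
    """Genes x cells log-normalized expression.

    value(g, c) = ln(1 + scale_factor * count(g, c) / total(c)); zeros in
    the count matrix stay exactly zero, so the sparsity pattern is shared
    with the counts it was derived from.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = _check_ids(self.gene_ids, "gene ids")
        self.cell_ids = _check_ids(self.cell_ids, "cell ids")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError("expression matrix shape inconsistent with ids")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        self._gene_index: dict | None = None

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        """Row indices of the given gene ids (KeyError on unknown genes)."""
        if self._gene_index is None:
            self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([self._gene_index[g] for g in genes], dtype=int)

    def cell_index(self, cells) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        return np.array([lookup[c] for c in cells], dtype=int)

    def dense(self, gene_rows=None, cell_cols=None) -> np.ndarray:
        """Dense sub-block (by integer indices); use for small selections."""
        m = self.values
        if gene_rows is not None:
            m = m[np.asarray(gene_rows, dtype=int), :]
        if cell_cols is not None:
            m = m[:, np.asarray(cell_cols, dtype=int)]
        return np.asarray(m.todense())


def validate_annotation(annot: pd.DataFrame, cell_ids=None) -> pd.DataFrame:
    """Validate a per-cell annotation table.

    Requires columns sample_id, condition, cell_type (tissue, timepoint
    and batch are optional and default to a single level); the index (or
    a cell_id column) must cover every matrix cell exactly once, and
    condition must be one of control / perturbed / treated.
    """
    annot = annot.copy()
    if "cell_id" in annot.columns:
        annot = annot.set_index("cell_id")
    missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in annot.columns]
    if missing:
        raise FormatError(f"annotation missing required columns: {missing}")
    for col, default in (("tissue", "tissue"), ("timepoint", "t0"), ("batch", "b0")):
        if col not in annot.columns:
            annot[col] = default
    bad = set(annot["condition"]) - set(CONDITIONS)
    if bad:
        raise FormatError(
            f"condition values {sorted(bad)} not in allowed set {CONDITIONS}"
        )
    if annot.index.duplicated().any():
        raise FormatError("annotation has duplicated cell ids")
    if cell_ids is not None:
        missing_cells = set(cell_ids) - set(annot.index)
        if missing_cells:
            raise FormatError(
                f"{len(missing_cells)} matrix cells lack annotation rows "
                f"(e.g. {sorted(missing_cells)[:3]})"
            )
        annot = annot.loc[list(cell_ids)]
    return annot
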