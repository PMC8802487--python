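"""QC filtering and library-size log2 normalization of count matrices.

The QC pass mirrors common droplet scRNA-seq practice: drop cells with too
few expressed genes, drop cells whose per-cell summaries (log2 total counts,
log2 number of expressed genes) deviate from the dataset median by more than
``mad_k`` median absolute deviations, then drop genes expressed in too few
of the surviving cells.  "Expressed" means a count strictly greater than 0.

Doublet-score and mitochondrial-fraction filters require external tooling or
genome annotation and are intentionally not part of this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .matrix import GeneExpressionMatrix


@dataclass
class QCParams:
    """Thresholds for :func:`qc_filter`.

    ``mad_constant`` scales the raw MAD; the default 1.0 uses the raw median
    absolute deviation (set 1.4826 for the normal-consistent estimate).
    """

    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 20
    mad_k: float = 3.0
    qc_metrics: tuple[str, ...] = ("log2_total", "log2_n_genes")
    mad_constant: float = 1.0

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ValueError("count thresholds must be >= 0")
        if self.mad_k < 0:
            raise ValueError("mad_k must be >= 0")
        unknown = set(self.qc_metrics) - {"log2_total", "log2_n_genes"}
        if unknown:
            raise ValueError(f"unknown QC metrics: {sorted(unknown)}")


def _per_cell_stats(values) -> tuple[np.ndarray, np.ndarray]:
    """(total counts, number of expressed genes) per cell."""
    if sparse.issparse(values):
        totals = np.asarray(values.sum(axis=0)).ravel()
        n_genes = np.asarray((values > 0).sum(axis=0)).ravel()
    else:
        totals = values.sum(axis=0)
        n_genes = (values > 0).sum(axis=0)
    return totals.astype(float), n_genes.astype(float)


def _mad_outliers(x: np.ndarray, k: float, constant: float) -> np.ndarray:
    """Boolean mask of entries deviating more than k MADs from the median."""
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * constant
    return np.abs(x - med) > k * mad


def qc_filter(mat: GeneExpressionMatrix, params: QCParams | None = None) -> GeneExpressionMatrix:
    """Apply cell filters then gene filters to a count matrix, once.

    Order: (1) cells with fewer than ``min_genes_per_cell`` expressed genes
    are removed; (2) among the survivors, cells deviating more than
    ``mad_k`` MADs from the median of each enabled QC metric are removed;
    (3) genes expressed in fewer than ``min_cells_per_gene`` of the
    remaining cells are removed.  Survivor order is preserved.

    Raises
    ------
    ValueError
        If the input is not counts, or nothing survives (the message counts
        each filter's casualties).
    """
    if params is None:
        params = QCParams()
    if mat.value_kind != "counts":
        raise ValueError("qc_filter requires a counts matrix")

    totals, n_expressed = _per_cell_stats(mat.values)
    keep_cells = n_expressed >= params.min_genes_per_cell
    n_drop_min_genes = int((~keep_cells).sum())

    n_drop_mad = 0
    if keep_cells.any() and params.qc_metrics:
        idx = np.flatnonzero(keep_cells)
        with np.errstate(divide="ignore"):
            metrics = {
                "log2_total": np.log2(totals[idx]),
                "log2_n_genes": np.log2(n_expressed[idx]),
            }
        out = np.zeros(len(idx), dtype=bool)
        for name in params.qc_metrics:
            out |= _mad_outliers(metrics[name], params.mad_k, params.mad_constant)
        keep_cells[idx[out]] = False
        n_drop_mad = int(out.sum())

    sub = mat.subset(cells=keep_cells) if not keep_cells.all() else mat
    if sub.n_cells == 0:
        raise ValueError(
            "no cells survive QC "
            f"({n_drop_min_genes} failed min_genes_per_cell, {n_drop_mad} MAD outliers)"
        )

    values = sub.values
    if sparse.issparse(values):
        cells_per_gene = np.asarray((values > 0).sum(axis=1)).ravel()
    else:
        cells_per_gene = (values > 0).sum(axis=1)
    keep_genes = cells_per_gene >= params.min_cells_per_gene
    n_drop_genes = int((~keep_genes).sum())
    if not keep_genes.any():
        raise ValueError(
            "no genes survive QC "
            f"({n_drop_min_genes} cells failed min_genes_per_cell, "
            f"{n_drop_mad} cells were MAD outliers, {n_drop_genes} genes "
            f"below min_cells_per_gene)"
        )
    if not keep_genes.all():
        sub = sub.subset(genes=keep_genes)
    return sub


def normalize_log2(mat: GeneExpressionMatrix, pseudocount: float = 1.0) -> GeneExpressionMatrix:
    """Library-size normalize and log2 transform a count matrix.

    Size factor per cell = (cell total) / (mean of cell totals), so factors
    average to 1 across the dataset.  Output value for gene g, cell j is
    ``log2(count[g, j] / sf[j] + pseudocount)``; ``value_kind`` becomes
    ``"log2norm"``.  With the default pseudocount of 1 a zero count maps to
    exactly 0 and sparse input stays sparse.

    Raises
    ------
    ValueError
        If the input is not counts or a cell has zero total (named in the
        message).
    """
    if mat.value_kind != "counts":
        raise ValueError("normalize_log2 requires a counts matrix")
    totals, _ = _per_cell_stats(mat.values)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = ", ".join(str(mat.cell_ids[i]) for i in zero[:5])
        raise ValueError(f"cells with zero total counts cannot be normalized: {names}")
    sf = totals / totals.mean()
    if sparse.issparse(mat.values) and pseudocount == 1.0:
        scaled = mat.values.tocsc(copy=True).astype(float)
        # scale each column (cell) by 1/sf without densifying
        scaled = scaled @ sparse.diags(1.0 / sf)
        scaled = scaled.tocsc()
        scaled.data = np.log2(scaled.data + 1.0)
        return mat.with_values(scaled, value_kind="log2norm")
    dense = mat.dense() / sf
    with np.errstate(divide="ignore"):
        out = np.log2(dense + pseudocount)
    return mat.with_values(out, value_kind="log2norm")
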