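"""Gene x cell expression container.

A deliberately small structure: a numeric matrix (dense ndarray or scipy
sparse) with gene annotations on rows and cell IDs on columns, plus a flag
saying whether values are raw counts or library-size-normalized log2
expression.  Downstream code never guesses which scale it is on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import sparse

VALUE_KINDS = ("counts", "log2norm")


@dataclass
class GeneExpressionMatrix:
    """A genes x cells expression matrix with row/column annotations.

    Parameters
    ----------
    values
        2-D numeric array or scipy sparse matrix, genes as rows.
    cell_ids
        Unique string identifier per cell (column).
    gene_ids
        Stable identifier per gene (e.g. Ensembl ID); may be ``None`` if
        only symbols are available.
    gene_symbols
        Gene symbol per gene; may be ``None`` if only IDs are available.
    batch
        Optional categorical label per cell (sample / batch of origin).
    value_kind
        ``"counts"`` (non-negative) or ``"log2norm"`` (finite).
    """

    values: np.ndarray | sparse.spmatrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray | None = None
    gene_symbols: np.ndarray | None = None
    batch: np.ndarray | None = None
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        if not sparse.issparse(self.values):
            self.values = np.asarray(self.values)
            if self.values.ndim != 2:
                raise ValueError("values must be a 2-D genes x cells matrix")
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"matrix has {n_cells} columns but {len(self.cell_ids)} cell IDs"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell IDs are not allowed")
        if self.gene_ids is None and self.gene_symbols is None:
            raise ValueError("at least one of gene_ids/gene_symbols is required")
        for name in ("gene_ids", "gene_symbols"):
            ann = getattr(self, name)
            if ann is not None:
                ann = np.asarray(ann, dtype=object)
                setattr(self, name, ann)
                if len(ann) != n_genes:
                    raise ValueError(
                        f"matrix has {n_genes} rows but {len(ann)} entries in {name}"
                    )
        if self.batch is not None:
            self.batch = np.asarray(self.batch, dtype=object)
            if len(self.batch) != n_cells:
                raise ValueError("batch labels must have one entry per cell")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}")
        if self.value_kind == "counts":
            mn = self.values.min() if self.values.size else 0
            if mn < 0:
                raise ValueError("counts must be non-negative")
        else:
            dense = self.values.toarray() if sparse.issparse(self.values) else self.values
            if dense.size and not np.all(np.isfinite(dense)):
                raise ValueError("log2norm values must be finite")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_keys(self) -> np.ndarray:
        """Preferred display key per gene: stable ID where present, else symbol."""
        if self.gene_ids is None:
            return self.gene_symbols.copy()
        if self.gene_symbols is None:
            return self.gene_ids.copy()
        keys = self.gene_ids.copy()
        missing = np.array([k is None or k == "" for k in keys])
        keys[missing] = self.gene_symbols[missing]
        return keys

    def dense(self) -> np.ndarray:
        """Values as a dense float ndarray (copy only when sparse)."""
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    # -- subsetting --------------------------------------------------------

    def subset(
        self,
        genes: Sequence[int] | np.ndarray | None = None,
        cells: Sequence[int] | np.ndarray | None = None,
    ) -> "GeneExpressionMatrix":
        """Return a new matrix restricted to the given row/column indices.

        Indices may be integer arrays or boolean masks; order is preserved
        as given (integer indices may reorder).
        """
        values = self.values
        gene_ids, gene_symbols = self.gene_ids, self.gene_symbols
        cell_ids, batch = self.cell_ids, self.batch
        if genes is not None:
            genes = np.asarray(genes)
            values = values[genes, :]
            if gene_ids is not None:
                gene_ids = gene_ids[genes]
            if gene_symbols is not None:
                gene_symbols = gene_symbols[genes]
        if cells is not None:
            cells = np.asarray(cells)
            values = values[:, cells]
            cell_ids = cell_ids[cells]
            if batch is not None:
                batch = batch[cells]
        return GeneExpressionMatrix(
            values=values,
            cell_ids=cell_ids,
            gene_ids=gene_ids,
            gene_symbols=gene_symbols,
            batch=batch,
            value_kind=self.value_kind,
        )

    def with_values(self, values, value_kind: str | None = None) -> "GeneExpressionMatrix":
        """Copy of this matrix with new values (same annotations)."""
        return replace(
            self, values=values, value_kind=value_kind or self.value_kind
        )
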