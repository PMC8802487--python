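"""Learning and serializing the fixed 2-D cell-cycle reference embedding.

The reference is learned once, on a dataset where the cell cycle dominates
transcriptional variation: restrict to a cell-cycle gene set, keep the top
``n`` most variable genes, mean-center each gene and take the top-2
principal directions in gene space.  The resulting o x 2 weight matrix R is
the whole transferable object — new datasets are projected through it
without refitting (see :mod:`cyclepos.projection`).

On disk a reference is a CSV (gene_id, gene_symbol, pc1, pc2) plus a JSON
sidecar with provenance metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import GeneExpressionMatrix


@dataclass
class ReferenceEmbedding:
    """Ordered gene keys with the fixed o x 2 projection weights R."""

    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    weights: np.ndarray  # o x 2
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        o = self.weights.shape[0]
        if self.weights.ndim != 2 or self.weights.shape[1] != 2:
            raise ValueError("weights must be an o x 2 matrix")
        if o < 2:
            raise ValueError("a reference needs at least 2 genes")
        if len(self.gene_ids) != o or len(self.gene_symbols) != o:
            raise ValueError("gene annotations must match the weight matrix rows")
        keys = list(zip(self.gene_ids, self.gene_symbols))
        if len(set(keys)) != o:
            raise ValueError("duplicate gene keys in reference")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("reference weights must be finite")

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]


def select_variable_genes(
    mat: GeneExpressionMatrix, gene_set, n: int = 500
) -> np.ndarray:
    """Indices of the top-``n`` most variable genes within ``gene_set``.

    Genes are matched to the set by stable ID first, then by symbol, and
    ranked by unbiased (n-1) sample variance of their log2 expression
    across cells, descending.  Ties keep input row order.  If fewer than
    ``n`` genes match, all matches are returned.
    """
    if mat.value_kind != "log2norm":
        raise ValueError("variable-gene selection expects log2-normalized values")
    keys = set(gene_set)
    if not keys:
        raise ValueError("gene_set is empty")
    matched = np.zeros(mat.n_genes, dtype=bool)
    if mat.gene_ids is not None:
        matched |= np.array([g in keys for g in mat.gene_ids])
    if mat.gene_symbols is not None:
        matched |= np.array([g in keys for g in mat.gene_symbols])
    idx = np.flatnonzero(matched)
    if idx.size == 0:
        sample = sorted(keys)[:5]
        raise ValueError(f"no genes of the gene set found in the matrix; first keys: {sample}")
    dense = mat.subset(genes=idx).dense()
    var = dense.var(axis=1, ddof=1) if dense.shape[1] > 1 else np.zeros(idx.size)
    order = np.argsort(-var, kind="stable")
    return idx[order[:n]]


def learn_reference(
    mat: GeneExpressionMatrix,
    gene_set,
    n: int = 500,
    source: str = "unspecified",
    integrated: bool = False,
) -> ReferenceEmbedding:
    """Learn the 2-D reference embedding from a log2-normalized matrix.

    Subset to the selected variable genes, subtract each gene's mean across
    cells, and take the top-2 left singular vectors of the centered
    genes x cells matrix: the gene-space directions of maximal variance.
    Sign convention: each component is flipped so its largest-magnitude
    loading is positive (recorded in ``meta``).

    ``integrated`` records whether the caller claims the matrix was batch
    integrated beforehand; no integration is performed here.
    """
    if mat.n_cells < 3:
        raise ValueError("learning a reference requires at least 3 cells")
    idx = select_variable_genes(mat, gene_set, n=n)
    sub = mat.subset(genes=idx)
    x = sub.dense()
    x = x - x.mean(axis=1, keepdims=True)
    nonzero = (x != 0).any(axis=1)
    if nonzero.sum() < 2:
        raise ValueError("fewer than 2 selected genes have nonzero variance")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    weights = u[:, :2].copy()
    for i in range(2):
        lead = np.argmax(np.abs(weights[:, i]))
        if weights[lead, i] < 0:
            weights[:, i] = -weights[:, i]
    total_var = float(np.sum(s**2))
    from . import __version__

    meta = {
        "source": source,
        "n_cells": int(mat.n_cells),
        "n_genes": int(len(idx)),
        "variance_explained": [float(s[0] ** 2 / total_var), float(s[1] ** 2 / total_var)],
        "sign_convention": "largest-abs-loading-positive",
        "integrated": bool(integrated),
        "version": __version__,
    }
    ids = sub.gene_ids if sub.gene_ids is not None else np.array([""] * len(idx), dtype=object)
    symbols = (
        sub.gene_symbols
        if sub.gene_symbols is not None
        else np.array([""] * len(idx), dtype=object)
    )
    return ReferenceEmbedding(gene_ids=ids, gene_symbols=symbols, weights=weights, meta=meta)


def write_reference(ref: ReferenceEmbedding, path) -> Path:
    """Write a reference as CSV plus a ``<path>.json`` metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "gene_id": ref.gene_ids,
            "gene_symbol": ref.gene_symbols,
            "pc1": ref.weights[:, 0],
            "pc2": ref.weights[:, 1],
        }
    )
    df.to_csv(path, index=False)
    Path(str(path) + ".json").write_text(json.dumps(ref.meta, indent=2))
    return path


def read_reference(path) -> ReferenceEmbedding:
    """Read a reference CSV (and its JSON sidecar, if present).

    Raises ``ValueError`` if required columns are missing or gene keys are
    duplicated.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"gene_id": str, "gene_symbol": str}, float_precision="round_trip")
    required = {"gene_id", "gene_symbol", "pc1", "pc2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference CSV is missing columns: {sorted(missing)}")
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ReferenceEmbedding(
        gene_ids=df["gene_id"].fillna("").to_numpy(dtype=object),
        gene_symbols=df["gene_symbol"].fillna("").to_numpy(dtype=object),
        weights=df[["pc1", "pc2"]].to_numpy(dtype=float),
        meta=meta,
    )


def training_scores(mat: GeneExpressionMatrix, ref: ReferenceEmbedding) -> np.ndarray:
    """PCA scores of the training matrix under its own reference.

    Convenience used for self-consistency checks: equals projecting the
    training matrix through ``ref`` with its own gene means.
    """
    from .projection import map_genes, project

    mapping = map_genes(ref, mat)
    return project(mat, ref, mapping).P
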