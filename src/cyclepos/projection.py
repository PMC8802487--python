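"""Projecting a new dataset into the fixed reference embedding.

Gene mapping matches reference genes to dataset rows (stable ID first, then
symbol; case-insensitive symbol-only in cross-species mode).  Projection is
a plain matrix product ``P = E~^t R``: the dataset restricted to matched
genes, each gene centered by its own mean across this dataset's cells, times
the matched rows of the reference weights.  Reference rows without a match
are silently dropped — no imputation, no weight renormalization.

Cell-cycle position is then the polar angle of each row of P, taken with the
two-argument arctangent and mapped into [0, 2*pi).  A cell landing exactly
at the origin has no defined angle and gets NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import GeneExpressionMatrix
from .reference import ReferenceEmbedding

TWO_PI = 2.0 * np.pi

DEFAULT_MIN_OVERLAP = 50
DEFAULT_WARN_OVERLAP = 200


@dataclass
class GeneMapping:
    """Result of matching reference genes to dataset rows."""

    ref_idx: np.ndarray  # indices into the reference, length o'
    data_idx: np.ndarray  # indices into the dataset, length o'
    status: list[str]  # per reference gene: by_id | by_symbol | missing

    @property
    def n_matched(self) -> int:
        return len(self.ref_idx)


@dataclass
class EmbeddingCoords:
    """Projected 2-D coordinates with the mapping that produced them."""

    P: np.ndarray  # cells x 2
    mapping: GeneMapping
    cell_ids: np.ndarray

    @property
    def matched_genes(self) -> int:
        return self.mapping.n_matched


@dataclass
class CellCyclePosition:
    """Per-cell angle theta in [0, 2*pi) (NaN where undefined)."""

    theta: np.ndarray
    coords: EmbeddingCoords


def map_genes(
    ref: ReferenceEmbedding,
    mat: GeneExpressionMatrix,
    cross_species: bool = False,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    warn_overlap: int = DEFAULT_WARN_OVERLAP,
) -> GeneMapping:
    """Match reference genes to dataset rows.

    Within-species: stable ID has priority, symbol is the fallback.
    Cross-species: case-insensitive symbol matching only (homologous gene
    symbols).  Each dataset row is used at most once.

    Raises ``ValueError`` if fewer than ``min_overlap`` genes match; warns
    below ``warn_overlap``.
    """
    id_lookup: dict = {}
    if mat.gene_ids is not None:
        for i, g in enumerate(mat.gene_ids):
            if g not in (None, "") and g not in id_lookup:
                id_lookup[g] = i
    sym_lookup: dict = {}
    if mat.gene_symbols is not None:
        for i, g in enumerate(mat.gene_symbols):
            if g in (None, ""):
                continue
            key = str(g).upper() if cross_species else g
            if key not in sym_lookup:
                sym_lookup[key] = i

    used: set[int] = set()
    ref_idx: list[int] = []
    data_idx: list[int] = []
    status: list[str] = []
    for r in range(ref.n_genes):
        hit = None
        how = "missing"
        if not cross_species:
            gid = ref.gene_ids[r]
            if gid not in (None, "") and gid in id_lookup and id_lookup[gid] not in used:
                hit, how = id_lookup[gid], "by_id"
        if hit is None:
            sym = ref.gene_symbols[r]
            if sym not in (None, ""):
                key = str(sym).upper() if cross_species else sym
                if key in sym_lookup and sym_lookup[key] not in used:
                    hit, how = sym_lookup[key], "by_symbol"
        status.append(how)
        if hit is not None:
            used.add(hit)
            ref_idx.append(r)
            data_idx.append(hit)

    n = len(ref_idx)
    if n < min_overlap:
        raise ValueError(
            f"only {n} of {ref.n_genes} reference genes matched the dataset "
            f"(minimum {min_overlap}); check gene identifiers"
        )
    if n < warn_overlap and n < ref.n_genes:
        warnings.warn(
            f"only {n} of {ref.n_genes} reference genes matched; the projected "
            "embedding's shape may be distorted",
            stacklevel=2,
        )
    return GeneMapping(
        ref_idx=np.asarray(ref_idx, dtype=int),
        data_idx=np.asarray(data_idx, dtype=int),
        status=status,
    )


def project(
    mat: GeneExpressionMatrix,
    ref: ReferenceEmbedding,
    mapping: GeneMapping | None = None,
    center_means: np.ndarray | None = None,
    **map_kwargs,
) -> EmbeddingCoords:
    """Project a log2-normalized matrix through the reference weights.

    ``center_means`` overrides the per-gene centering means (one per matched
    gene, in mapping order); by default each gene is centered by its mean
    across this dataset's cells.
    """
    if mat.value_kind != "log2norm":
        raise ValueError("projection expects a log2-normalized matrix")
    if mapping is None:
        mapping = map_genes(ref, mat, **map_kwargs)
    if mapping.n_matched == 0:
        raise ValueError("gene mapping is empty")
    e = mat.subset(genes=mapping.data_idx).dense()
    if center_means is None:
        center_means = e.mean(axis=1)
    else:
        center_means = np.asarray(center_means, dtype=float)
        if center_means.shape != (mapping.n_matched,):
            raise ValueError("center_means must have one entry per matched gene")
    e_centered = e - center_means[:, None]
    if not (e_centered != 0).any():
        warnings.warn(
            "all matched genes are constant across cells; projection is "
            "degenerate (P = 0, theta undefined)",
            stacklevel=2,
        )
    p = e_centered.T @ ref.weights[mapping.ref_idx]
    return EmbeddingCoords(P=p, mapping=mapping, cell_ids=mat.cell_ids.copy())


def theta_from_coords(coords: EmbeddingCoords) -> CellCyclePosition:
    """Polar angle of each projected cell, in [0, 2*pi).

    Uses the two-argument arctangent (quadrant aware).  Cells at exactly
    (0, 0) get NaN and are named in a warning.
    """
    p = coords.P
    at_origin = (p[:, 0] == 0) & (p[:, 1] == 0)
    theta = np.mod(np.arctan2(p[:, 1], p[:, 0]), TWO_PI)
    if at_origin.any():
        ids = [str(c) for c in coords.cell_ids[at_origin][:10]]
        warnings.warn(
            f"{int(at_origin.sum())} cells sit at the embedding origin; their "
            "cell-cycle position is undefined (NaN): " + ", ".join(ids),
            stacklevel=2,
        )
        theta = theta.copy()
        theta[at_origin] = np.nan
    return CellCyclePosition(theta=theta, coords=coords)


def estimate_cycle_position(
    mat: GeneExpressionMatrix,
    ref: ReferenceEmbedding,
    cross_species: bool = False,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> CellCyclePosition:
    """Map genes, project, and compute theta in one call."""
    mapping = map_genes(ref, mat, cross_species=cross_species, min_overlap=min_overlap)
    coords = project(mat, ref, mapping)
    return theta_from_coords(coords)
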