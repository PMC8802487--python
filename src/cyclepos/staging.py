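"""Five-stage marker-based cell-cycle stage assignment.

Stages form the fixed cycle G1S -> S -> G2 -> G2M -> MG1 -> G1S.  For each
stage a curated marker-gene list is first *pruned*: a gene survives only if
its expression correlates (Pearson r > 0.2 by default) with the mean
expression of its own list, which removes markers that do not co-vary with
the stage program in this particular dataset.  Stage scores are the mean
log2 expression over the pruned list, z-scored across cells (rows) and then
across the five stages (columns).  A cell keeps its argmax stage label only
if the runner-up stage is cyclically adjacent AND the score margin between
the top two exceeds a threshold (0.3 by default); otherwise the label is NA.

Because the scores are doubly z-scored and the pruning uses correlations,
the whole pipeline is invariant to per-batch location/scale shifts — it is
nevertheless run separately per batch when batch labels are available, which
also guards against batch-specific pruning differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .matrix import GeneExpressionMatrix

STAGES = ("G1S", "S", "G2", "G2M", "MG1")
NA_LABEL = "NA"

DEFAULT_PRUNE_THRESHOLD = 0.2
FALLBACK_PRUNE_THRESHOLD = 0.15  # for very shallow data with weak co-expression
DEFAULT_MARGIN = 0.3


@dataclass
class StageGeneLists:
    """Raw (and optionally pruned) marker lists for the five stages."""

    lists: dict[str, list[str]]
    pruned: dict[str, list[str]] | None = None
    prune_threshold: float = DEFAULT_PRUNE_THRESHOLD

    def __post_init__(self) -> None:
        missing = set(STAGES) - set(self.lists)
        if missing:
            raise ValueError(f"missing stage lists: {sorted(missing)}")
        if self.pruned is not None:
            for k in STAGES:
                extra = set(self.pruned.get(k, [])) - set(self.lists[k])
                if extra:
                    raise ValueError(f"pruned list for {k} contains unknown genes: {sorted(extra)}")


def _match_rows(mat: GeneExpressionMatrix, keys: list[str]) -> np.ndarray:
    """Dataset row index for each key matched by ID or symbol (order kept)."""
    lookup: dict = {}
    for ann in (mat.gene_ids, mat.gene_symbols):
        if ann is not None:
            for i, g in enumerate(ann):
                if g not in (None, "") and g not in lookup:
                    lookup[g] = i
    return np.array([lookup[k] for k in keys if k in lookup], dtype=int)


def prune_stage_genes(
    mat: GeneExpressionMatrix,
    lists: StageGeneLists,
    threshold: float | None = None,
) -> StageGeneLists:
    """Prune each stage list to genes that co-vary with their list mean.

    For stage k with matched genes g, compute the per-cell mean m_k over
    the list and keep g iff Pearson cor(E_g, m_k) > threshold.

    Raises ``ValueError`` if a stage list matches no genes, or prunes to
    empty (the message suggests the sparse-data fallback threshold 0.15).
    """
    if mat.value_kind != "log2norm":
        raise ValueError("stage assignment expects a log2-normalized matrix")
    if threshold is None:
        threshold = lists.prune_threshold
    dense = mat.dense()
    pruned: dict[str, list[str]] = {}
    for stage in STAGES:
        keys = lists.lists[stage]
        rows = _match_rows(mat, keys)
        if rows.size == 0:
            raise ValueError(f"stage {stage}: no marker genes found in the matrix")
        present = set_of_matched(mat, keys)
        matched_keys = [k for k in keys if k in present]
        sub = dense[rows]
        m_k = sub.mean(axis=0)
        kept: list[str] = []
        m_sd = m_k.std()
        for key, row in zip(matched_keys, sub):
            sd = row.std()
            if sd == 0 or m_sd == 0:
                continue
            r = np.corrcoef(row, m_k)[0, 1]
            if r > threshold:
                kept.append(key)
        if not kept:
            raise ValueError(
                f"stage {stage}: every marker was pruned at threshold {threshold}; "
                f"shallowly sequenced data may need threshold {FALLBACK_PRUNE_THRESHOLD}"
            )
        pruned[stage] = kept
    return replace(lists, pruned=pruned, prune_threshold=threshold)


def set_of_matched(mat: GeneExpressionMatrix, keys: list[str]) -> set:
    """Subset of ``keys`` present in the matrix (by ID or symbol)."""
    present: set = set()
    for ann in (mat.gene_ids, mat.gene_symbols):
        if ann is not None:
            present |= {g for g in ann if g not in (None, "")}
    return {k for k in keys if k in present}


def _zscore(x: np.ndarray, axis: int, ddof: int = 1) -> np.ndarray:
    mean = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero variance encountered while z-scoring stage scores")
    return (x - mean) / sd


def stage_scores(
    mat: GeneExpressionMatrix, pruned: StageGeneLists
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (A) and doubly z-scored (A~) 5 x cells stage score matrices.

    A[k, j] is the mean log2 expression of the pruned stage-k list in cell
    j.  A~ z-scores each row across cells (sample sd), then each column
    across the five stages.
    """
    if pruned.pruned is None:
        raise ValueError("stage lists must be pruned first (prune_stage_genes)")
    dense = mat.dense()
    raw = np.empty((len(STAGES), mat.n_cells))
    for i, stage in enumerate(STAGES):
        rows = _match_rows(mat, pruned.pruned[stage])
        if rows.size == 0:
            raise ValueError(f"stage {stage}: pruned list matches no genes")
        raw[i] = dense[rows].mean(axis=0)
    tilde = _zscore(_zscore(raw, axis=1), axis=0)
    return raw, tilde


def assign_stages(a_tilde: np.ndarray, margin: float = DEFAULT_MARGIN) -> np.ndarray:
    """Per-cell stage labels from the doubly z-scored score matrix.

    The argmax stage is kept only if (i) the runner-up stage is cyclically
    adjacent (MG1 and G1S are neighbors) and (ii) the top-two score gap
    exceeds ``margin``; otherwise NA.  Exact top ties give NA.
    """
    a_tilde = np.asarray(a_tilde, dtype=float)
    if a_tilde.shape[0] != len(STAGES):
        raise ValueError(f"score matrix must have {len(STAGES)} rows")
    n = a_tilde.shape[1]
    labels = np.full(n, NA_LABEL, dtype=object)
    order = np.argsort(-a_tilde, axis=0, kind="stable")
    top, second = order[0], order[1]
    top_score = a_tilde[top, np.arange(n)]
    second_score = a_tilde[second, np.arange(n)]
    ties = top_score == second_score
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} cells have tied top stage scores; assigned NA",
            stacklevel=2,
        )
    adjacent = np.minimum((top - second) % len(STAGES), (second - top) % len(STAGES)) == 1
    keep = adjacent & (top_score - second_score > margin) & ~ties
    labels[keep] = np.array(STAGES, dtype=object)[top[keep]]
    return labels


def stage_cells(
    mat: GeneExpressionMatrix,
    lists: StageGeneLists,
    threshold: float | None = None,
    margin: float = DEFAULT_MARGIN,
) -> np.ndarray:
    """Full prune -> score -> assign pipeline on one (sub)dataset."""
    pruned = prune_stage_genes(mat, lists, threshold=threshold)
    _, tilde = stage_scores(mat, pruned)
    return assign_stages(tilde, margin=margin)


def assign_stages_batched(
    mat: GeneExpressionMatrix,
    lists: StageGeneLists,
    batch: np.ndarray | None = None,
    threshold: float | None = None,
    margin: float = DEFAULT_MARGIN,
) -> np.ndarray:
    """Run the stage pipeline independently per batch.

    ``batch`` defaults to ``mat.batch``; with no batch labels the whole
    matrix is one batch.  Batches with fewer than 3 cells get all-NA labels
    with a warning.  Labels are returned in the original cell order.
    """
    if batch is None:
        batch = mat.batch
    if batch is None:
        return stage_cells(mat, lists, threshold=threshold, margin=margin)
    batch = np.asarray(batch, dtype=object)
    if len(batch) != mat.n_cells:
        raise ValueError("batch labels must cover all cells")
    labels = np.full(mat.n_cells, NA_LABEL, dtype=object)
    for b in dict.fromkeys(batch):  # preserves first-seen order
        sel = np.flatnonzero(batch == b)
        if sel.size < 3:
            warnings.warn(
                f"batch {b!r} has only {sel.size} cells; assigning NA", stacklevel=2
            )
            continue
        labels[sel] = stage_cells(
            mat.subset(cells=sel), lists, threshold=threshold, margin=margin
        )
    return labels
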