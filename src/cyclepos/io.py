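"""Readers and writers for the on-disk formats the tool touches.

Supported matrix formats:

* Matrix Market (``.mtx``) with genes as rows, accompanied by a
  ``features.tsv`` (gene_id, gene_symbol[, feature_type], no header) and a
  ``barcodes.tsv`` (one cell barcode per line) — the 10x Genomics layout.
* Dense CSV/TSV with the gene key in the first column and cell IDs in the
  header row.

Plus plain-text gene-set files (one key per line, ``#`` comments) and
stage-marker lists (five files or a single two-column TSV).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .matrix import GeneExpressionMatrix

_ENSEMBL_PREFIXES = ("ENSG", "ENSMUS", "ENST", "ENSMUST", "ERCC")


def _dedupe_genes(mat: GeneExpressionMatrix) -> GeneExpressionMatrix:
    """Keep the first row for each duplicated gene key, warning about the rest."""
    keys = mat.gene_keys()
    seen: set = set()
    keep = np.ones(mat.n_genes, dtype=bool)
    for i, k in enumerate(keys):
        if k in seen:
            keep[i] = False
        else:
            seen.add(k)
    if not keep.all():
        dropped = [str(k) for k, kp in zip(keys, keep) if not kp]
        warnings.warn(
            f"dropped {len(dropped)} duplicated gene keys (kept first occurrence): "
            + ", ".join(sorted(set(dropped))[:5]),
            stacklevel=3,
        )
        mat = mat.subset(genes=keep)
    return mat


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".tsv":
        return "tsv"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer matrix format from {path.name!r}; pass format=")


def read_matrix(
    path,
    format: str | None = None,
    features: str | Path | None = None,
    barcodes: str | Path | None = None,
    value_kind: str = "counts",
    key_kind: str = "auto",
) -> GeneExpressionMatrix:
    """Read a genes x cells matrix from MTX or dense CSV/TSV.

    Parameters
    ----------
    path
        The ``.mtx`` file (or a directory containing ``matrix.mtx``), or a
        dense CSV/TSV file.
    format
        ``"mtx"``, ``"csv"`` or ``"tsv"``; inferred from the suffix if omitted.
    features, barcodes
        For MTX: the annotation files.  Default to ``features.tsv`` and
        ``barcodes.tsv`` next to the matrix.
    value_kind
        Scale flag recorded on the returned matrix.
    key_kind
        For dense input, whether the first column holds stable IDs
        (``"id"``), symbols (``"symbol"``) or should be guessed (``"auto"``,
        from Ensembl-style prefixes).

    Raises
    ------
    ValueError
        On dimension mismatch between matrix and annotation files, or
        duplicate cell IDs.  Duplicate gene keys keep the first row with a
        warning.
    """
    path = Path(path)
    if path.is_dir():
        path = path / "matrix.mtx"
    if format is None:
        format = _infer_format(path)
    if format == "mtx":
        features = Path(features) if features else path.parent / "features.tsv"
        barcodes = Path(barcodes) if barcodes else path.parent / "barcodes.tsv"
        values = sparse.csc_matrix(spio.mmread(path))
        feat = pd.read_csv(features, sep="\t", header=None, dtype=str)
        if feat.shape[1] < 2:
            feat[1] = feat[0]
        bc = pd.read_csv(barcodes, sep="\t", header=None, dtype=str)
        if feat.shape[0] != values.shape[0]:
            raise ValueError(
                f"features file has {feat.shape[0]} rows but matrix has "
                f"{values.shape[0]} genes"
            )
        if bc.shape[0] != values.shape[1]:
            raise ValueError(
                f"barcodes file has {bc.shape[0]} rows but matrix has "
                f"{values.shape[1]} cells"
            )
        mat = GeneExpressionMatrix(
            values=values,
            cell_ids=bc[0].to_numpy(),
            gene_ids=feat[0].to_numpy(),
            gene_symbols=feat[1].to_numpy(),
            value_kind=value_kind,
        )
        return _dedupe_genes(mat)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            raise ValueError("duplicate cell IDs in header")
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        keys = df.index.to_numpy(dtype=object)
        if key_kind == "auto":
            n_ens = sum(str(k).upper().startswith(_ENSEMBL_PREFIXES) for k in keys)
            key_kind = "id" if n_ens >= max(1, len(keys) // 2) else "symbol"
        kwargs = {"gene_ids": keys} if key_kind == "id" else {"gene_symbols": keys}
        mat = GeneExpressionMatrix(
            values=df.to_numpy(dtype=float),
            cell_ids=df.columns.to_numpy(dtype=object),
            value_kind=value_kind,
            **kwargs,
        )
        return _dedupe_genes(mat)
    raise ValueError(f"unknown matrix format {format!r}")


def write_matrix(mat: GeneExpressionMatrix, path, format: str | None = None) -> Path:
    """Write a matrix as MTX (+features/barcodes) or dense CSV/TSV.

    For MTX, ``path`` is a directory; ``matrix.mtx``, ``features.tsv`` and
    ``barcodes.tsv`` are created inside it.  Returns the path of the matrix
    file written.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if (path.suffix == "" or path.suffix == ".mtx") else _infer_format(path)
    if format == "mtx":
        outdir = path.parent if path.suffix == ".mtx" else path
        outdir.mkdir(parents=True, exist_ok=True)
        mtx_path = outdir / "matrix.mtx" if path.suffix != ".mtx" else path
        values = mat.values if sparse.issparse(mat.values) else sparse.coo_matrix(mat.values)
        spio.mmwrite(mtx_path, values)
        ids = mat.gene_ids if mat.gene_ids is not None else mat.gene_symbols
        symbols = mat.gene_symbols if mat.gene_symbols is not None else mat.gene_ids
        feat = pd.DataFrame({"id": ids, "symbol": symbols})
        feat.to_csv(mtx_path.parent / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(mat.cell_ids).to_csv(
            mtx_path.parent / "barcodes.tsv", sep="\t", header=False, index=False
        )
        return mtx_path
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(mat.dense(), index=mat.gene_keys(), columns=mat.cell_ids)
        df.to_csv(path, sep=sep)
        return path
    raise ValueError(f"unknown matrix format {format!r}")


def read_gene_set(path) -> list[str]:
    """Read a gene-set file: one key per line, ``#`` starts a comment."""
    keys: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            keys.append(line)
    return keys


def read_stage_lists(source) -> dict[str, list[str]]:
    """Read five-stage marker lists.

    ``source`` is either a mapping ``{stage: path}`` of per-stage gene-set
    files, or a single two-column TSV (``stage<TAB>gene``, optional header).
    Returns ``{stage: [gene keys]}``.
    """
    if isinstance(source, Mapping):
        return {stage: read_gene_set(p) for stage, p in source.items()}
    df = pd.read_csv(Path(source), sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("stage-list TSV needs two columns: stage, gene")
    if df.iloc[0, 0].lower() in ("stage", "phase"):
        df = df.iloc[1:]
    lists: dict[str, list[str]] = {}
    for stage, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        lists.setdefault(stage, []).append(gene)
    return lists
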