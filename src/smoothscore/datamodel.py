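"""Core containers: expression datasets, gene sets, and score tables.

The central object is :class:`ExpressionDataset`, a sparse cells x genes
count matrix with aligned cell annotations.  Counts are accepted as
non-negative reals rather than forced to integers, because smoothed or
re-normalized matrices are routinely re-scored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionDataset",
    "GeneSet",
    "FormatError",
    "ValidationError",
    "load_dataset",
    "write_dataset",
    "write_scores",
    "MISSING_GROUP_LABEL",
]

#: Label given to cells whose groupby value is missing; they form their own
#: group instead of being dropped.
MISSING_GROUP_LABEL = "(missing)"


class FormatError(ValueError):
    """An on-disk file does not match the expected format or dimensions."""


class ValidationError(ValueError):
    """In-memory data violates a container invariant."""


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class ExpressionDataset:
    """Sparse cells x genes counts with aligned per-cell annotations.

    Parameters
    ----------
    counts
        Non-negative matrix, one row per cell, one column per gene.  Stored
        as CSR; dense input is converted.
    gene_ids, cell_ids
        Ordered, duplicate-free identifier lists matching the matrix axes.
    cell_annotations
        One row per cell, same order as ``counts`` rows, indexed by cell id.
        Created empty when omitted.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts contain negative entries")
        if self.cell_annotations is None:
            self.cell_annotations = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            ann = self.cell_annotations
            missing = set(self.cell_ids) - set(ann.index.astype(str))
            if missing:
                raise ValidationError(
                    f"annotations missing for {len(missing)} cells, e.g. {sorted(missing)[:5]}"
                )
            ann = ann.loc[[str(c) for c in self.cell_ids]]
            ann.index = pd.Index(self.cell_ids, name="cell_id")
            self.cell_annotations = ann

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, idx: np.ndarray) -> "ExpressionDataset":
        """Dataset restricted to the cells at integer positions ``idx``."""
        idx = np.asarray(idx)
        return ExpressionDataset(
            counts=self.counts[idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_annotations=self.cell_annotations.iloc[idx],
        )


@dataclass(frozen=True)
class GeneSet:
    """A named signature with up-regulated and optional down-regulated genes.

    ``mode`` is derived: ``two-part`` when both halves are non-empty,
    otherwise ``up-only`` / ``down-only``.
    """

    name: str
    up_genes: frozenset = frozenset()
    down_genes: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_genes", frozenset(self.up_genes))
        object.__setattr__(self, "down_genes", frozenset(self.down_genes))
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValidationError(
                f"gene set {self.name!r}: genes in both halves: {sorted(overlap)[:5]}"
            )
        if not self.up_genes and not self.down_genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    @property
    def mode(self) -> str:
        if self.up_genes and self.down_genes:
            return "two-part"
        return "up-only" if self.up_genes else "down-only"

    @property
    def all_genes(self) -> frozenset:
        return self.up_genes | self.down_genes


def _read_ids(path: str) -> list[str]:
    with open(path) as fh:
        ids = [line.strip() for line in fh]
    # 10x-style feature files may carry extra tab-separated columns; the
    # first field is the identifier.
    return [i.split("\t")[0] for i in ids if i]


def load_dataset(
    counts_path: str,
    genes_path: str,
    cells_path: str,
    annotations_path: str | None = None,
    orientation: str | None = None,
) -> ExpressionDataset:
    """Load a dataset from Matrix Market counts plus ID and annotation files.

    Orientation is decided by matching matrix dimensions against the ID file
    lengths: a genes x cells matrix (the common 10x convention) is
    transposed.  A square matrix with equal ID counts is ambiguous and
    requires ``orientation`` ("cells-by-genes" or "genes-by-cells").
    """
    mat = scipy.io.mmread(counts_path)
    genes = _read_ids(genes_path)
    cells = _read_ids(cells_path)
    r, c = mat.shape
    if orientation is not None:
        if orientation not in ("cells-by-genes", "genes-by-cells"):
            raise ValueError(f"unknown orientation {orientation!r}")
        transpose = orientation == "genes-by-cells"
    elif (r, c) == (len(cells), len(genes)) and (r, c) != (len(genes), len(cells)):
        transpose = False
    elif (r, c) == (len(genes), len(cells)) and (r, c) != (len(cells), len(genes)):
        transpose = True
    elif (r, c) == (len(cells), len(genes)):  # square and ambiguous
        raise FormatError(
            f"{counts_path}: square {r}x{c} matrix with {len(genes)} genes and "
            f"{len(cells)} cells is ambiguous; pass an explicit orientation"
        )
    else:
        raise FormatError(
            f"{counts_path}: matrix is {r}x{c} but ID files give "
            f"{len(genes)} genes ({genes_path}) and {len(cells)} cells ({cells_path})"
        )
    if transpose:
        mat = mat.T
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(cells), len(genes)):
        raise FormatError(
            f"{counts_path}: oriented matrix is {mat.shape[0]}x{mat.shape[1]}, "
            f"expected {len(cells)} cells x {len(genes)} genes"
        )
    ann = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", dtype=str)
        ann = ann.set_index(ann.columns[0])
    return ExpressionDataset(mat, genes, cells, ann)


def write_dataset(ds: ExpressionDataset, out_dir: str, prefix: str = "") -> dict:
    """Write a dataset as MTX + ID lists + annotation TSV; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "counts": os.path.join(out_dir, f"{prefix}counts.mtx"),
        "genes": os.path.join(out_dir, f"{prefix}genes.txt"),
        "cells": os.path.join(out_dir, f"{prefix}cells.txt"),
        "annotations": os.path.join(out_dir, f"{prefix}annotations.tsv"),
    }
    scipy.io.mmwrite(paths["counts"], ds.counts.tocoo())
    for key, ids in (("genes", ds.gene_ids), ("cells", ds.cell_ids)):
        with open(paths[key], "w") as fh:
            fh.write("\n".join(ids) + "\n")
    ann = ds.cell_annotations.reset_index()
    ann.to_csv(paths["annotations"], sep="\t", index=False)
    return paths


def write_scores(scores: pd.DataFrame, path: str) -> None:
    """Write a score table as TSV with ``cell_id`` as the first column."""
    out = scores.copy()
    out.index.name = "cell_id"
    out.reset_index().to_csv(path, sep="\t", index=False)
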