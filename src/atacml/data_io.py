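"""Domain containers and on-disk formats for accessibility datasets.

A dataset is a sparse cells x genes matrix of gene "existence status"
(1 = at least one accessible segment maps to the gene in that cell,
0 = none), plus per-cell type labels.  On disk it is a Matrix Market
coordinate file (1-based indices, the sparse single-cell convention),
a headered TSV of cell metadata and a plain-text gene list.
"""

from __future__ import annotations

import dataclasses
import os
from collections import Counter
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "AccessibilityDataset",
    "ClassSummary",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "summarize_classes",
]


class ValidationError(ValueError):
    """A dataset or file failed an integrity check."""


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


@dataclasses.dataclass
class AccessibilityDataset:
    """Sparse binary (or interpolated) cells x genes matrix with labels.

    Parameters
    ----------
    matrix
        CSR matrix, rows = cells, columns = genes.
    cell_ids, cell_types
        Per-row identifiers and class labels, aligned to rows.
    gene_ids
        Per-column identifiers.
    kind
        ``"binary"`` for raw inputs (strictly {0,1}), ``"fractional"``
        for SMOTE-augmented data (values in [0,1]), ``"real"`` for
        derived feature matrices such as autoencoder reconstructions.
    """

    matrix: sp.csr_matrix
    cell_ids: list[str]
    cell_types: list[str]
    gene_ids: list[str]
    kind: str = "binary"

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.cell_types = [str(c) for c in self.cell_types]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.validate()

    # -- integrity ---------------------------------------------------
    def validate(self) -> None:
        n, d = self.matrix.shape
        if n != len(self.cell_ids):
            raise ValidationError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if n != len(self.cell_types):
            raise ValidationError(
                f"matrix has {n} rows but {len(self.cell_types)} cell type labels"
            )
        if d != len(self.gene_ids):
            raise ValidationError(
                f"matrix has {d} columns but {len(self.gene_ids)} gene ids"
            )
        dup = _first_duplicate(self.cell_ids)
        if dup is not None:
            raise ValidationError(f"duplicate cell id: {dup!r}")
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValidationError(f"duplicate gene id: {dup!r}")
        data = self.matrix.data
        if self.kind == "binary":
            bad = data[(data != 0.0) & (data != 1.0)]
            if bad.size:
                raise ValidationError(
                    f"non-binary value {bad[0]!r} in a strict binary dataset"
                )
        elif self.kind == "fractional":
            if data.size and (data.min() < 0.0 or data.max() > 1.0):
                raise ValidationError("values outside [0,1] in fractional dataset")
        elif self.kind != "real":
            raise ValidationError(f"unknown dataset kind {self.kind!r}")
        if not np.all(np.isfinite(data)):
            raise ValidationError("non-finite values in matrix")

    # -- convenience -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.cell_types))

    def labels(self) -> np.ndarray:
        return np.asarray(self.cell_types, dtype=object)

    def dense(self, feature_ids: Sequence[str] | None = None) -> np.ndarray:
        """Dense float matrix, optionally restricted to named columns."""
        if feature_ids is None:
            return self.matrix.toarray()
        idx = self.gene_index(feature_ids)
        return self.matrix[:, idx].toarray()

    def gene_index(self, feature_ids: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.asarray([pos[f] for f in feature_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown gene id: {exc.args[0]!r}") from None

    def subset_genes(self, feature_ids: Sequence[str]) -> "AccessibilityDataset":
        idx = self.gene_index(feature_ids)
        return AccessibilityDataset(
            matrix=self.matrix[:, idx],
            cell_ids=list(self.cell_ids),
            cell_types=list(self.cell_types),
            gene_ids=[self.gene_ids[i] for i in idx],
            kind=self.kind,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AccessibilityDataset):
            return NotImplemented
        return (
            self.cell_ids == other.cell_ids
            and self.cell_types == other.cell_types
            and self.gene_ids == other.gene_ids
            and (self.matrix != other.matrix).nnz == 0
        )


@dataclasses.dataclass(frozen=True)
class ClassSummary:
    """Per-class cell counts and the max/min imbalance ratio."""

    counts: dict[str, int]
    imbalance_ratio: float

    @property
    def n_classes(self) -> int:
        return len(self.counts)


def summarize_classes(ds: AccessibilityDataset) -> ClassSummary:
    """Count cells per class and compute the imbalance ratio (max/min)."""
    if ds.n_cells == 0:
        raise ValidationError("cannot summarize an empty dataset")
    counts = dict(sorted(Counter(ds.cell_types).items()))
    values = list(counts.values())
    return ClassSummary(counts=counts, imbalance_ratio=max(values) / min(values))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_dataset(
    matrix_path: str | os.PathLike,
    cells_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    *,
    strict_binary: bool = True,
    transpose: bool = False,
) -> AccessibilityDataset:
    """Read a dataset from Matrix Market + TSV metadata + gene list.

    ``transpose`` reads gene-row (cellranger-style) matrices into the
    fixed cells-as-rows orientation.  ``strict_binary=False`` accepts
    fractional values in [0,1] (e.g. re-reading SMOTE output).
    """
    mat = sp.csr_matrix(scipy.io.mmread(os.fspath(matrix_path)))
    if transpose:
        mat = sp.csr_matrix(mat.T)
    cells = pd.read_csv(cells_path, sep="\t", dtype=str)
    for col in ("cell_id", "cell_type"):
        if col not in cells.columns:
            raise ValidationError(f"cells file lacks required column {col!r}")
    gene_ids = [
        line.strip()
        for line in Path(genes_path).read_text().splitlines()
        if line.strip()
    ]
    return AccessibilityDataset(
        matrix=mat,
        cell_ids=cells["cell_id"].tolist(),
        cell_types=cells["cell_type"].tolist(),
        gene_ids=gene_ids,
        kind="binary" if strict_binary else "fractional",
    )


def write_dataset(ds: AccessibilityDataset, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write matrix.mtx, cells.tsv and genes.txt consumable by read_dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "cells": out / "cells.tsv",
        "genes": out / "genes.txt",
    }
    coo = ds.matrix.tocoo()
    integral = ds.kind == "binary"
    if integral:
        scipy.io.mmwrite(paths["matrix"], coo.astype(np.int64), field="integer")
    else:
        scipy.io.mmwrite(paths["matrix"], coo, field="real", precision=17)
    pd.DataFrame({"cell_id": ds.cell_ids, "cell_type": ds.cell_types}).to_csv(
        paths["cells"], sep="\t", index=False, lineterminator="\n"
    )
    paths["genes"].write_text("\n".join(ds.gene_ids) + "\n")
    return paths
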