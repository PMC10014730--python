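"""Synthetic imbalanced multiclass binary accessibility matrices.

The generator emulates the structure of a gene-level single-cell
accessibility matrix: each class (cell type) owns a small disjoint set
of marker genes that are accessible with high probability ``p_on`` in
cells of that class, every other gene is background-accessible with
probability ``p_bg``, and an optional symmetric bit-flip models assay
noise.  Class sizes may be heavily imbalanced (the real atlases show up
to a 70-fold spread between the largest and smallest cell type).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp

from .data_io import AccessibilityDataset, ValidationError

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset", "imbalanced_sizes"]


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-marker generator.

    ``class_sizes`` gives the number of cells per class (length
    ``n_classes``).  Marker sets are pairwise disjoint: class ``c``
    owns genes ``g{c*mpc} .. g{(c+1)*mpc - 1}``.
    """

    n_classes: int
    class_sizes: tuple[int, ...]
    n_genes: int
    markers_per_class: int
    p_on: float = 0.9
    p_bg: float = 0.1
    flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValidationError("n_classes must be positive")
        if len(self.class_sizes) != self.n_classes:
            raise ValidationError("class_sizes length must equal n_classes")
        if any(s < 1 for s in self.class_sizes):
            raise ValidationError("class sizes must be positive")
        if not (0.0 <= self.p_bg < self.p_on <= 1.0):
            raise ValidationError("require 0 <= p_bg < p_on <= 1")
        if not (0.0 <= self.flip_rate < 0.5):
            raise ValidationError("require 0 <= flip_rate < 0.5")
        if self.markers_per_class < 0:
            raise ValidationError("markers_per_class must be non-negative")
        if self.markers_per_class * self.n_classes > self.n_genes:
            raise ValidationError("marker genes exceed total genes")

    @property
    def n_cells(self) -> int:
        return int(sum(self.class_sizes))


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Planted marker genes per class."""

    markers: dict[str, list[str]]

    def all_markers(self) -> list[str]:
        out: list[str] = []
        for cls in sorted(self.markers):
            out.extend(self.markers[cls])
        return out


def class_label(i: int) -> str:
    return f"class{i:02d}"


def imbalanced_sizes(n_classes: int, max_size: int, ratio: float, seed: int = 0) -> list[int]:
    """Per-class counts spanning ``max_size`` down to ``max_size/ratio``.

    The largest class has exactly ``max_size`` cells, the smallest
    ``round(max_size / ratio)``, and the remaining classes are drawn
    log-uniformly between the two extremes — mimicking the long-tailed
    per-type counts of real cell atlases.  Returned sorted descending.
    """
    if ratio < 1:
        raise ValidationError("ratio must be >= 1")
    if n_classes < 1:
        raise ValidationError("n_classes must be positive")
    min_size = max(int(round(max_size / ratio)), 1)
    if n_classes == 1:
        return [max_size]
    sizes = [max_size, min_size]
    if n_classes > 2:
        rng = np.random.default_rng(seed)
        logs = rng.uniform(np.log(min_size), np.log(max_size), size=n_classes - 2)
        sizes.extend(int(round(x)) for x in np.exp(logs))
    return sorted(sizes, reverse=True)


def generate_dataset(cfg: SyntheticConfig) -> tuple[AccessibilityDataset, GroundTruth]:
    """Draw a dataset from the planted-marker model.

    Marker genes of a cell's own class are Bernoulli(``p_on``), all
    other genes Bernoulli(``p_bg``); every bit is then flipped
    independently with probability ``flip_rate``.  Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_cells, cfg.n_genes
    gene_ids = [f"g{j:04d}" for j in range(d)]
    cell_types: list[str] = []
    for c, size in enumerate(cfg.class_sizes):
        cell_types.extend([class_label(c)] * size)
    cell_ids = [f"cell{i:05d}" for i in range(n)]

    prob = np.full((n, d), cfg.p_bg)
    markers: dict[str, list[str]] = {}
    row = 0
    for c, size in enumerate(cfg.class_sizes):
        lo = c * cfg.markers_per_class
        hi = lo + cfg.markers_per_class
        markers[class_label(c)] = gene_ids[lo:hi]
        prob[row : row + size, lo:hi] = cfg.p_on
        row += size

    bits = (rng.random((n, d)) < prob).astype(np.int8)
    if cfg.flip_rate > 0:
        flips = rng.random((n, d)) < cfg.flip_rate
        bits = np.where(flips, 1 - bits, bits)

    ds = AccessibilityDataset(
        matrix=sp.csr_matrix(bits.astype(np.float64)),
        cell_ids=cell_ids,
        cell_types=cell_types,
        gene_ids=gene_ids,
        kind="binary",
    )
    return ds, GroundTruth(markers=markers)
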