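"""Performance measures, SMOTE balancing and cross-validated evaluation.

The headline statistic is the multiclass Matthews correlation
coefficient: prediction and truth label vectors are one-hot encoded
into N x K binary matrices X and Y and the MCC is the correlation

    MCC = cov(X, Y) / sqrt(cov(X, X) * cov(Y, Y)),

where cov(A, B) = (1/K) * sum_{n,k} (A_nk - mean_k(A)) (B_nk - mean_k(B)).
This equals Gorodkin's R_K statistic and reduces to the textbook binary
MCC for K = 2.  Constant predictions (or single-class truth) make a
variance term zero; by convention the score is then 0 ("like random
predictions").
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .data_io import AccessibilityDataset

__all__ = [
    "SmoteParams",
    "PerformanceRecord",
    "ClassifierSpec",
    "build_classifier",
    "multiclass_mcc",
    "overall_accuracy",
    "per_class_accuracy",
    "smote_balance",
    "stratified_fold_assignment",
    "cross_validated_performance",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _as_labels(v: Sequence) -> np.ndarray:
    arr = np.asarray(list(v), dtype=object)
    if arr.size == 0:
        raise ValueError("empty label vector")
    return arr


def multiclass_mcc(pred: Sequence, truth: Sequence) -> float:
    """Multiclass MCC from one-hot covariance; 0 when a variance vanishes."""
    p, t = _as_labels(pred), _as_labels(truth)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.size} predictions vs {t.size} truths")
    classes = sorted(set(p) | set(t))
    index = {c: k for k, c in enumerate(classes)}
    n, k = p.size, len(classes)
    X = np.zeros((n, k))
    Y = np.zeros((n, k))
    X[np.arange(n), [index[c] for c in p]] = 1.0
    Y[np.arange(n), [index[c] for c in t]] = 1.0
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    cov_xy = float(np.sum(Xc * Yc))
    cov_xx = float(np.sum(Xc * Xc))
    cov_yy = float(np.sum(Yc * Yc))
    if cov_xx == 0.0 or cov_yy == 0.0:
        return 0.0
    return cov_xy / np.sqrt(cov_xx * cov_yy)


def overall_accuracy(pred: Sequence, truth: Sequence) -> float:
    """Fraction of samples whose predicted class equals the true class."""
    p, t = _as_labels(pred), _as_labels(truth)
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    return float(np.mean(p == t))


def per_class_accuracy(pred: Sequence, truth: Sequence) -> dict[str, float]:
    """Per-class recall; classes absent from the truth are omitted."""
    p, t = _as_labels(pred), _as_labels(truth)
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    out: dict[str, float] = {}
    for cls in sorted(set(t)):
        mask = t == cls
        out[cls] = float(np.mean(p[mask] == t[mask]))
    return out


@dataclasses.dataclass(frozen=True)
class PerformanceRecord:
    """Pooled cross-validation performance of one classifier."""

    mcc: float
    acc: float
    per_class_accuracy: dict[str, float]
    n_features: int
    classifier_name: str


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ClassifierSpec:
    """Named classifier with backend hyperparameters.

    ``"dt"`` is CART with Gini impurity; ``"rf"`` a bagged CART
    ensemble (100 trees by default), majority-vote aggregation.
    """

    name: str
    params: Mapping[str, object] = dataclasses.field(default_factory=dict)


def build_classifier(spec: ClassifierSpec, seed: int):
    params = dict(spec.params)
    if spec.name == "dt":
        return DecisionTreeClassifier(criterion="gini", random_state=seed, **params)
    if spec.name == "rf":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(
            criterion="gini", random_state=seed, n_jobs=1, **params
        )
    raise ValueError(f"unknown classifier name {spec.name!r}")


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SmoteParams:
    """Synthetic minority oversampling parameters.

    New minority samples are x + u * (x_nbr - x) with u ~ U[0,1] and
    x_nbr one of the k nearest same-class neighbours (Euclidean).
    ``target_count=None`` balances every class up to the largest.
    """

    k_neighbors: int = 5
    target_count: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _smote_rows(X: np.ndarray, n_new: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Interpolated rows within one class; X holds that class only."""
    n = X.shape[0]
    k_eff = min(k, n - 1)
    # pairwise Euclidean distances within the class
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, np.inf)
    nbr = np.argsort(d2, axis=1, kind="stable")[:, :k_eff]
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(0, k_eff, size=n_new)
    u = rng.random(n_new)
    anchors = X[base]
    partners = X[nbr[base, pick]]
    return anchors + u[:, None] * (partners - anchors)


def smote_balance(ds: AccessibilityDataset, params: SmoteParams) -> AccessibilityDataset:
    """Oversample every class up to the target count; originals untouched."""
    X = ds.matrix.toarray()
    y = ds.labels()
    counts = Counter(ds.cell_types)
    target = params.target_count if params.target_count is not None else max(counts.values())
    rng = np.random.default_rng(params.seed)

    new_rows: list[np.ndarray] = []
    new_ids: list[str] = []
    new_types: list[str] = []
    for cls in sorted(counts):
        deficit = target - counts[cls]
        if deficit <= 0:
            continue
        if counts[cls] < 2:
            raise ValueError(
                f"class {cls!r} has a single sample; SMOTE needs a neighbour"
            )
        if params.k_neighbors > counts[cls] - 1:
            warnings.warn(
                f"k_neighbors clipped to {counts[cls] - 1} for class {cls!r}",
                stacklevel=2,
            )
        rows = _smote_rows(X[y == cls], deficit, params.k_neighbors, rng)
        new_rows.append(rows)
        new_ids.extend(f"{cls}_smote_{i:05d}" for i in range(deficit))
        new_types.extend([cls] * deficit)

    if not new_rows:
        return ds
    stacked = np.vstack([X] + new_rows)
    kind = ds.kind if ds.kind == "real" else "fractional"
    return AccessibilityDataset(
        matrix=sp.csr_matrix(stacked),
        cell_ids=list(ds.cell_ids) + new_ids,
        cell_types=list(ds.cell_types) + new_types,
        gene_ids=list(ds.gene_ids),
        kind=kind,
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def stratified_fold_assignment(labels: Sequence, folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold ids.

    Indices of each class are shuffled and dealt round-robin, so a
    class with fewer members than ``folds`` simply contributes to that
    many folds.
    """
    y = _as_labels(labels)
    rng = np.random.default_rng(seed)
    assignment = np.empty(y.size, dtype=np.intp)
    offset = 0
    for cls in sorted(set(y)):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = (np.arange(idx.size) + offset) % folds
        offset += idx.size  # stagger classes so folds stay balanced
    return assignment


def cross_validated_performance(
    ds: AccessibilityDataset,
    feature_ids: Sequence[str],
    classifier_spec: ClassifierSpec,
    folds: int = 10,
    smote: SmoteParams | None = None,
    seed: int = 0,
    fold_assignment: np.ndarray | None = None,
) -> PerformanceRecord:
    """Stratified k-fold CV on a fixed feature subset, pooled scoring.

    SMOTE, when requested, is applied to the training portion of each
    fold only (no synthetic samples ever reach a test fold) unless the
    caller balanced the dataset globally beforehand.  Predictions are
    pooled across folds before computing MCC / ACC / per-class
    accuracy.  Deterministic given ``seed``.
    """
    sub = ds.subset_genes(feature_ids)
    y = sub.labels()
    if len(set(y)) < 2:
        raise ValueError("cross-validation needs at least 2 classes")
    if fold_assignment is None:
        fold_assignment = stratified_fold_assignment(y, folds, seed)
    X = sub.matrix.toarray()

    pooled_pred = np.empty(y.size, dtype=object)
    for f in range(folds):
        test = fold_assignment == f
        if not test.any():
            continue
        train = ~test
        X_tr, y_tr = X[train], y[train]
        if smote is not None:
            train_ds = AccessibilityDataset(
                matrix=sp.csr_matrix(X_tr),
                cell_ids=[f"tr{i}" for i in range(X_tr.shape[0])],
                cell_types=list(y_tr),
                gene_ids=list(sub.gene_ids),
                kind=sub.kind if sub.kind == "real" else "fractional",
            )
            balanced = smote_balance(
                train_ds, dataclasses.replace(smote, seed=smote.seed + f)
            )
            X_tr, y_tr = balanced.matrix.toarray(), balanced.labels()
        clf = build_classifier(classifier_spec, seed)
        clf.fit(X_tr, y_tr)
        pooled_pred[test] = clf.predict(X[test])

    evaluated = np.array([p is not None for p in pooled_pred])
    pred = pooled_pred[evaluated]
    truth = y[evaluated]
    return PerformanceRecord(
        mcc=multiclass_mcc(pred, truth),
        acc=overall_accuracy(pred, truth),
        per_class_accuracy=per_class_accuracy(pred, truth),
        n_features=len(feature_ids),
        classifier_name=classifier_spec.name,
    )
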