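"""Incremental feature selection over a ranked feature list.

Prefixes of sizes step, 2*step, ... floor(d/step)*step are evaluated by
stratified 10-fold cross-validation; the prefix maximizing the pooled
multiclass MCC is the optimal feature subset.  One fold partition,
derived from the stage seed, is shared across every subset size of a
curve so the curve reflects feature-set changes only.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import AccessibilityDataset
from .evaluation import (
    ClassifierSpec,
    PerformanceRecord,
    SmoteParams,
    build_classifier,
    cross_validated_performance,
    smote_balance,
    stratified_fold_assignment,
)
from .ranking import FeatureRanking

__all__ = ["IFSCurve", "FittedModel", "build_subsets", "run_ifs", "select_optimal", "fit_final"]


@dataclasses.dataclass
class IFSCurve:
    """Per-subset-size cross-validated performance records."""

    records: list[tuple[int, PerformanceRecord]]
    step: int
    provenance: dict = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path: str | Path) -> None:
        classes = sorted(
            {c for _, rec in self.records for c in rec.per_class_accuracy}
        )
        rows = []
        for n, rec in self.records:
            row: dict = {"n_features": n, "mcc": rec.mcc, "acc": rec.acc}
            for c in classes:
                row[f"acc_{c}"] = rec.per_class_accuracy.get(c, np.nan)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclasses.dataclass
class FittedModel:
    """Final classifier restricted to an optimal feature prefix."""

    classifier: object
    feature_ids: list[str]
    spec: ClassifierSpec
    seed: int

    def predict(self, ds: AccessibilityDataset) -> np.ndarray:
        return self.classifier.predict(ds.dense(self.feature_ids))


def build_subsets(ranking: FeatureRanking, step: int) -> list[list[str]]:
    """Nested prefixes of sizes step, 2*step, ..., floor(d/step)*step.

    The floor convention drops a trailing remainder shorter than one
    step (a list of 3,897 features at step 5 yields 779 subsets).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if len(ranking) == 0:
        raise ValueError("empty ranking")
    return [
        ranking.top(n) for n in range(step, len(ranking) + 1, step)
    ]


def run_ifs(
    ds: AccessibilityDataset,
    ranking: FeatureRanking,
    classifier_spec: ClassifierSpec,
    step: int,
    folds: int = 10,
    smote: SmoteParams | None = None,
    seed: int = 0,
) -> IFSCurve:
    """Evaluate every prefix subset; deterministic given seed."""
    missing = set(ranking.feature_ids) - set(ds.gene_ids)
    if missing:
        raise KeyError(f"ranking features absent from dataset: {sorted(missing)[:3]}")
    fold_assignment = stratified_fold_assignment(ds.labels(), folds, seed)
    records = []
    for subset in build_subsets(ranking, step):
        rec = cross_validated_performance(
            ds,
            subset,
            classifier_spec,
            folds=folds,
            smote=smote,
            seed=seed,
            fold_assignment=fold_assignment,
        )
        records.append((len(subset), rec))
    return IFSCurve(
        records=records,
        step=step,
        provenance={
            "ranking_stage": ranking.stage,
            "classifier": classifier_spec.name,
            "folds": folds,
            "seed": seed,
            "smote": dataclasses.asdict(smote) if smote else None,
        },
    )


def select_optimal(curve: IFSCurve) -> tuple[int, PerformanceRecord]:
    """Record with maximum MCC; ties broken toward fewer features."""
    if not curve.records:
        raise ValueError("empty IFS curve")
    return max(curve.records, key=lambda nr: (nr[1].mcc, -nr[0]))


def fit_final(
    ds: AccessibilityDataset,
    ranking: FeatureRanking,
    n_features: int,
    classifier_spec: ClassifierSpec,
    smote: SmoteParams | None = None,
    seed: int = 0,
) -> FittedModel:
    """Fit the final classifier on all cells using the top-n prefix."""
    if n_features > len(ranking):
        raise ValueError("n_features exceeds ranking length")
    features = ranking.top(n_features)
    train = ds.subset_genes(features)
    if smote is not None:
        train = smote_balance(train, smote)
    clf = build_classifier(classifier_spec, seed)
    clf.fit(train.matrix.toarray(), train.labels())
    return FittedModel(
        classifier=clf, feature_ids=features, spec=classifier_spec, seed=seed
    )
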