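"""All-relevant feature screening with shadow features.

Each iteration permutes every candidate column to make "shadow"
copies, fits a random forest on [originals | shadows], and records a
hit for each original feature whose impurity importance exceeds the
best shadow importance.  A two-sided binomial test (p = 0.5) on the
accumulated hit counts, Bonferroni-corrected over the features still
undecided, confirms features with significantly many hits and rejects
those with significantly few.  The loop ends when every feature is
decided or ``max_iter`` is reached; survivors stay tentative.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

from .data_io import AccessibilityDataset

__all__ = ["BorutaDecision", "make_shadows", "boruta_select"]

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"


@dataclasses.dataclass
class BorutaDecision:
    """Outcome of the screening loop."""

    status: dict[str, str]  # feature id -> confirmed | rejected | tentative
    hits: dict[str, int]
    iterations: int
    alpha: float
    max_iter: int

    def features_with(self, status: str) -> list[str]:
        return [f for f, s in self.status.items() if s == status]

    @property
    def confirmed(self) -> list[str]:
        return self.features_with(CONFIRMED)

    @property
    def rejected(self) -> list[str]:
        return self.features_with(REJECTED)

    @property
    def tentative(self) -> list[str]:
        return self.features_with(TENTATIVE)

    def selected(self, keep_tentative: bool = False) -> list[str]:
        out = self.confirmed
        if keep_tentative:
            out = out + self.tentative
        return out

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "feature_id": list(self.status),
                "status": [self.status[f] for f in self.status],
                "hits": [self.hits[f] for f in self.status],
                "iterations": self.iterations,
            }
        ).to_csv(path, sep="\t", index=False, lineterminator="\n")

    def summary(self) -> dict:
        return {
            "n_confirmed": len(self.confirmed),
            "n_rejected": len(self.rejected),
            "n_tentative": len(self.tentative),
            "iterations": self.iterations,
            "alpha": self.alpha,
        }

    def summary_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2, sort_keys=True) + "\n")


def make_shadows(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One shadow column per original: an independent row permutation.

    Permuting breaks any association with the labels while preserving
    each column's value multiset (hence its marginal distribution).
    """
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("need a 2-D matrix with at least one column")
    shadows = np.empty_like(X)
    for j in range(X.shape[1]):
        shadows[:, j] = X[rng.permutation(X.shape[0]), j]
    return shadows


def boruta_select(
    ds: AccessibilityDataset,
    alpha: float = 0.05,
    max_iter: int = 100,
    seed: int = 0,
    n_estimators: int = 100,
) -> BorutaDecision:
    """Run the screening loop on all genes; deterministic given seed.

    Rejected features are dropped from subsequent forests; confirmed
    ones stay in the design matrix so importances remain comparable.
    """
    y = ds.labels()
    if len(set(y)) < 2:
        raise ValueError("boruta_select needs at least 2 classes")
    if ds.n_genes == 0:
        raise ValueError("no features to screen")
    X_full = ds.matrix.toarray()
    gene_ids = list(ds.gene_ids)
    d = len(gene_ids)

    rng = np.random.default_rng(seed)
    status = np.full(d, TENTATIVE, dtype=object)
    hits = np.zeros(d, dtype=int)
    iterations = 0

    for it in range(1, max_iter + 1):
        active = status != REJECTED  # confirmed + tentative compete
        tentative = np.flatnonzero(status == TENTATIVE)
        if tentative.size == 0:
            break
        iterations = it
        act_idx = np.flatnonzero(active)
        X = X_full[:, act_idx]
        shadows = make_shadows(X, rng)
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            criterion="gini",
            n_jobs=1,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        forest.fit(np.hstack([X, shadows]), y)
        imp = forest.feature_importances_
        orig_imp = imp[: act_idx.size]
        shadow_max = imp[act_idx.size :].max()
        hits[act_idx[orig_imp > shadow_max]] += 1

        # binomial decision on the still-undecided features
        n_tent = tentative.size
        for j in tentative:
            p = binomtest(int(hits[j]), it, 0.5, alternative="two-sided").pvalue
            if p * n_tent < alpha:
                status[j] = CONFIRMED if hits[j] > it / 2 else REJECTED

    return BorutaDecision(
        status={g: status[j] for j, g in enumerate(gene_ids)},
        hits={g: int(hits[j]) for j, g in enumerate(gene_ids)},
        iterations=iterations,
        alpha=alpha,
        max_iter=max_iter,
    )
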