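"""If-then classification rules read off a fitted decision tree.

Each root-to-leaf path becomes one rule: the path's split conditions
form the antecedent, the leaf majority class the consequent, and the
leaf's training-sample count and class purity quantify its reach.  On
binary accessibility features CART places every threshold at 0.5, so
conditions read "gene accessible (> 0.5)" / "inaccessible (<= 0.5)".
The rules of one tree tile the feature space: any complete feature row
matches exactly one rule, and that rule reproduces the tree's
prediction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = ["ClassificationRule", "RuleSet", "extract_rules", "apply_rules", "filter_rules"]

LE = "<="
GT = ">"


@dataclasses.dataclass(frozen=True)
class ClassificationRule:
    """One root-to-leaf path.

    ``conditions`` holds the merged (tightest-interval) form used for
    display; ``raw_conditions`` the unmerged path in split order, which
    is what ``apply_rules`` evaluates.
    """

    conditions: tuple[tuple[str, str, float], ...]
    raw_conditions: tuple[tuple[str, str, float], ...]
    predicted_class: str
    support: int
    purity: float

    def matches(self, row: dict[str, float]) -> bool:
        for feat, rel, thr in self.raw_conditions:
            val = row[feat]
            if rel == LE and not val <= thr:
                return False
            if rel == GT and not val > thr:
                return False
        return True

    def text(self) -> str:
        if not self.conditions:
            cond = "TRUE"
        else:
            cond = " AND ".join(f"{f} {r} {t:g}" for f, r, t in self.conditions)
        return f"IF {cond} THEN {self.predicted_class}"


@dataclasses.dataclass
class RuleSet:
    rules: list[ClassificationRule]
    class_labels: list[str]
    feature_ids: list[str]

    def __len__(self) -> int:
        return len(self.rules)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "rule_id": np.arange(1, len(self.rules) + 1),
                "predicted_class": [r.predicted_class for r in self.rules],
                "support": [r.support for r in self.rules],
                "purity": [r.purity for r in self.rules],
                "conditions": [
                    ";".join(f"{f}{rel}{thr:g}" for f, rel, thr in r.conditions)
                    for r in self.rules
                ],
            }
        ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _merge_conditions(
    raw: Sequence[tuple[str, str, float]]
) -> tuple[tuple[str, str, float], ...]:
    """Collapse repeated tests on one feature into the tightest bounds."""
    upper: dict[str, float] = {}
    lower: dict[str, float] = {}
    order: list[str] = []
    for feat, rel, thr in raw:
        if feat not in order:
            order.append(feat)
        if rel == LE:
            upper[feat] = min(upper.get(feat, np.inf), thr)
        else:
            lower[feat] = max(lower.get(feat, -np.inf), thr)
    merged: list[tuple[str, str, float]] = []
    for feat in order:
        if feat in lower:
            merged.append((feat, GT, lower[feat]))
        if feat in upper:
            merged.append((feat, LE, upper[feat]))
    return tuple(merged)


def extract_rules(
    tree: DecisionTreeClassifier, class_labels: Sequence[str] | None = None,
    feature_ids: Sequence[str] | None = None,
) -> RuleSet:
    """One rule per leaf of a fitted CART tree.

    Leaf-majority ties follow the fitted tree's own argmax convention
    (first class in ``classes_`` order, i.e. the lexicographically
    smallest label), which keeps rule predictions identical to the
    tree's and makes output deterministic.
    """
    check_is_fitted(tree)
    t = tree.tree_
    classes = [str(c) for c in tree.classes_]
    if class_labels is not None:
        classes = [str(c) for c in class_labels]
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(t.n_features)]
    feature_ids = list(feature_ids)

    def node_counts(node: int) -> np.ndarray:
        # recent sklearn stores class fractions in tree_.value; older
        # versions store weighted counts — normalise to counts either way
        v = t.value[node].ravel()
        if not np.isclose(v.sum(), t.weighted_n_node_samples[node]):
            v = v * t.weighted_n_node_samples[node]
        return v

    rules: list[ClassificationRule] = []

    def walk(node: int, path: list[tuple[str, str, float]]) -> None:
        if t.children_left[node] == -1:
            counts = node_counts(node)
            # ties resolve like the backend's argmax (first class in
            # classes_ order) so rules always reproduce tree predictions
            best = int(np.argmax(counts))
            support = int(round(t.weighted_n_node_samples[node]))
            rules.append(
                ClassificationRule(
                    conditions=_merge_conditions(path),
                    raw_conditions=tuple(path),
                    predicted_class=classes[best],
                    support=support,
                    purity=float(counts[best] / counts.sum()),
                )
            )
            return
        feat = feature_ids[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], path + [(feat, LE, thr)])
        walk(t.children_right[node], path + [(feat, GT, thr)])

    walk(0, [])
    return RuleSet(rules=rules, class_labels=classes, feature_ids=feature_ids)


def apply_rules(rules: RuleSet, cell: Sequence[float] | dict[str, float]) -> str:
    """Route one complete feature row; exactly one rule must match."""
    if not isinstance(cell, dict):
        cell = dict(zip(rules.feature_ids, cell))
    matched = [r for r in rules.rules if r.matches(cell)]
    if len(matched) != 1:
        raise ValueError(
            f"expected exactly one matching rule, found {len(matched)}"
        )
    return matched[0].predicted_class


def filter_rules(
    rules: RuleSet, min_support: int = 1, classes: set[str] | None = None
) -> RuleSet:
    """Drop low-support rules and, optionally, rules for other classes."""
    kept = [
        r
        for r in rules.rules
        if r.support >= min_support
        and (classes is None or r.predicted_class in classes)
    ]
    return RuleSet(rules=kept, class_labels=rules.class_labels, feature_ids=rules.feature_ids)
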