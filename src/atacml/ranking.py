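"""Ordered feature rankings with per-feature scores and provenance."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["FeatureRanking"]


@dataclasses.dataclass
class FeatureRanking:
    """Features sorted by a stage score, best first.

    ``stage`` records which ranking procedure produced the scores
    (e.g. ``"mcfs"`` relative importance or ``"tsplit"`` boosted-tree
    split counts).  Ties are broken lexicographically by feature id so
    rankings are reproducible.
    """

    feature_ids: list[str]
    scores: np.ndarray
    stage: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.feature_ids) != self.scores.size:
            raise ValueError("feature_ids and scores length mismatch")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids in ranking")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def top(self, n: int) -> list[str]:
        return self.feature_ids[:n]

    @classmethod
    def from_scores(cls, scores: Mapping[str, float], stage: str) -> "FeatureRanking":
        """Sort descending by score, ties broken by feature id."""
        items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(
            feature_ids=[k for k, _ in items],
            scores=np.array([v for _, v in items]),
            stage=stage,
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "feature_id": self.feature_ids,
                "score": self.scores,
            }
        ).to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path, stage: str = "loaded") -> "FeatureRanking":
        df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
        return cls(
            feature_ids=df["feature_id"].tolist(),
            scores=df["score"].to_numpy(),
            stage=stage,
        )
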