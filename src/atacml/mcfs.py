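"""Monte Carlo feature selection: relative-importance ranking.

Many small decision trees are grown on random feature projections and
random train/test splits.  Feature ``g`` accumulates, over all s*t
trees, the score

    RI_g = sum_trees  wAcc^u * sum_{nodes splitting on g}
              IG(node) * (n_node / n_root)^v

where ``wAcc`` is the tree's weighted accuracy on its held-out samples
(unweighted mean of per-class recall, so rare classes count equally)
and ``IG`` is the Gini impurity decrease at the node.  Features are
ranked by RI descending.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .data_io import AccessibilityDataset
from .ranking import FeatureRanking

__all__ = ["McfsParams", "tree_ri_contribution", "mcfs_rank"]


@dataclasses.dataclass(frozen=True)
class McfsParams:
    """Monte Carlo feature selection parameters.

    ``m`` features per random projection (default ~5% of the feature
    count, at least 2), ``t`` trees per projection, ``s`` projections,
    ``u``/``v`` the positive exponents weighting tree accuracy and node
    coverage, ``train_fraction`` the per-tree training split.
    """

    m: int | None = None
    t: int = 5
    s: int = 200
    u: float = 1.0
    v: float = 1.0
    train_fraction: float = 0.66
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t < 1 or self.s < 1:
            raise ValueError("s and t must be >= 1")
        if self.u <= 0 or self.v <= 0:
            raise ValueError("u and v must be positive")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0,1)")
        if self.m is not None and self.m < 1:
            raise ValueError("m must be >= 1")

    def resolve_m(self, n_features: int) -> int:
        if self.m is not None:
            if self.m > n_features:
                raise ValueError(f"m={self.m} exceeds feature count {n_features}")
            return self.m
        return min(max(int(np.ceil(0.05 * n_features)), 2), n_features)


def _node_gains(tree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-internal-node (feature index, impurity decrease, sample count)."""
    t = tree.tree_
    internal = t.children_left != -1
    idx = np.flatnonzero(internal)
    n = t.n_node_samples.astype(np.float64)
    left, right = t.children_left[idx], t.children_right[idx]
    gain = t.impurity[idx] - (
        n[left] * t.impurity[left] + n[right] * t.impurity[right]
    ) / n[idx]
    return t.feature[idx], gain, n[idx]


def tree_ri_contribution(
    tree: DecisionTreeClassifier,
    wAcc: float,
    params: McfsParams,
    feature_ids: list[str] | None = None,
) -> dict:
    """Per-feature RI contribution of one fitted tree.

    Keys are column indices, or ids when ``feature_ids`` is given;
    features the tree never splits on are absent (contribution 0).
    """
    features, gains, counts = _node_gains(tree)
    if features.size == 0:
        return {}
    root_n = float(tree.tree_.n_node_samples[0])
    weights = (wAcc ** params.u) * gains * (counts / root_n) ** params.v
    out: dict = {}
    for f, w in zip(features, weights):
        key = feature_ids[f] if feature_ids is not None else int(f)
        out[key] = out.get(key, 0.0) + float(w)
    return out


def _weighted_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Unweighted mean of per-class recall over classes present in truth."""
    recalls = [
        float(np.mean(pred[truth == c] == c)) for c in np.unique(truth)
    ]
    return float(np.mean(recalls))


def mcfs_rank(ds: AccessibilityDataset, params: McfsParams) -> FeatureRanking:
    """Rank all genes by aggregated relative importance.

    For each of ``s`` projections, ``m`` features are drawn uniformly
    without replacement; ``t`` trees are grown per projection, each on
    a fresh ``train_fraction`` split, scored on its held-out samples,
    and its node contributions accumulated into RI.  Deterministic
    given ``params.seed``.
    """
    y = ds.labels()
    if len(set(y)) < 2:
        raise ValueError("mcfs_rank needs at least 2 classes")
    d = ds.n_genes
    m = params.resolve_m(d)
    rng = np.random.default_rng(params.seed)
    X = ds.matrix.toarray()
    n = X.shape[0]
    n_train = max(int(round(params.train_fraction * n)), 1)
    if n_train >= n:
        n_train = n - 1

    ri = np.zeros(d)
    for _ in range(params.s):
        cols = rng.choice(d, size=m, replace=False)
        Xp = X[:, cols]
        for _ in range(params.t):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            tree = DecisionTreeClassifier(
                criterion="gini",
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(Xp[tr], y[tr])
            wacc = _weighted_accuracy(tree.predict(Xp[te]), y[te])
            for local, w in tree_ri_contribution(tree, wacc, params).items():
                ri[cols[local]] += w

    return FeatureRanking.from_scores(
        {g: float(ri[j]) for j, g in enumerate(ds.gene_ids)}, stage="mcfs"
    )
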