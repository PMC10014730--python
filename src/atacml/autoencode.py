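"""Pass-2 feature engineering: tied-weight autoencoder + T-split ranking.

The autoencoder maps an input row x (the pass-1 optimal features of one
cell) to an embedding y = f(W x + b) and reconstructs z = g(W^T y + b')
with the decoder sharing the transposed encoder weights.  Minibatch SGD
with momentum minimises the reconstruction loss (squared error by
default, absolute error optionally).  The reconstructed matrix z — one
column per input gene — is then ranked by the split counts of a
LightGBM multiclass ensemble: a feature's T-split score is the total
number of internal nodes across all K boosted trees that split on it.
The resulting ranking feeds a second, step-1 incremental feature
selection pass.
"""

from __future__ import annotations

import dataclasses

import lightgbm
import numpy as np
import scipy.sparse as sp

from .data_io import AccessibilityDataset
from .evaluation import ClassifierSpec, SmoteParams
from .ifs import FittedModel, IFSCurve, fit_final, run_ifs, select_optimal
from .ranking import FeatureRanking

__all__ = [
    "AEParams",
    "AEModel",
    "GbdtParams",
    "ReboostBundle",
    "train_autoencoder",
    "reconstruct",
    "tsplit_rank",
    "reboost_pipeline",
]

_ACTIVATIONS = {
    "identity": (lambda a: a, lambda a, out: np.ones_like(out)),
    "logistic": (lambda a: 1.0 / (1.0 + np.exp(-a)), lambda a, out: out * (1.0 - out)),
    "tanh": (np.tanh, lambda a, out: 1.0 - out * out),
}


@dataclasses.dataclass(frozen=True)
class AEParams:
    """Autoencoder training parameters.

    ``f_activation`` applies to the encoder, ``g_activation`` to the
    decoder output (identity keeps reconstructions unbounded, which is
    what the squared loss wants on centred data).  ``loss`` is
    ``"squared"`` or ``"absolute"``.
    """

    embed_dim: int = 64
    epochs: int = 200
    learning_rate: float = 0.05
    batch_size: int = 32
    momentum: float = 0.9
    f_activation: str = "logistic"
    g_activation: str = "identity"
    loss: str = "squared"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.f_activation not in _ACTIVATIONS or self.g_activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation; choose from {sorted(_ACTIVATIONS)}")
        if self.loss not in ("squared", "absolute"):
            raise ValueError("loss must be 'squared' or 'absolute'")


@dataclasses.dataclass
class AEModel:
    """Tied-weight encoder/decoder parameters and the training trace."""

    W: np.ndarray  # (embed_dim, d) encoder weights; decoder uses W.T
    b: np.ndarray  # (embed_dim,) encoder bias
    b_out: np.ndarray  # (d,) decoder bias
    params: AEParams
    loss_trace: list[float]

    @property
    def final_loss(self) -> float:
        return self.loss_trace[-1]


def _loss_value(X: np.ndarray, Z: np.ndarray, loss: str) -> float:
    if loss == "squared":
        return float(np.mean((Z - X) ** 2))
    return float(np.mean(np.abs(Z - X)))


def _forward(model_W, b, b_out, X, f_name, g_name):
    f, _ = _ACTIVATIONS[f_name]
    g, _ = _ACTIVATIONS[g_name]
    Y = f(X @ model_W.T + b)
    Z = g(Y @ model_W + b_out)
    return Y, Z


def train_autoencoder(features: np.ndarray, params: AEParams) -> AEModel:
    """Fit the tied-weight autoencoder by minibatch SGD; deterministic."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input")
    n, d = X.shape
    h = params.embed_dim
    rng = np.random.default_rng(params.seed)

    f, f_grad = _ACTIVATIONS[params.f_activation]
    g, g_grad = _ACTIVATIONS[params.g_activation]

    W = rng.normal(0.0, 1.0 / np.sqrt(d), size=(h, d))
    b = np.zeros(h)
    b_out = np.zeros(d)
    vW = np.zeros_like(W)
    vb = np.zeros_like(b)
    vb_out = np.zeros_like(b_out)

    trace: list[float] = []
    for _ in range(params.epochs):
        order = rng.permutation(n)
        for start in range(0, n, params.batch_size):
            idx = order[start : start + params.batch_size]
            Xb = X[idx]
            B = Xb.shape[0]
            pre_y = Xb @ W.T + b
            Y = f(pre_y)
            pre_z = Y @ W + b_out
            Z = g(pre_z)

            if params.loss == "squared":
                dZ = 2.0 * (Z - Xb) / (B * d)
            else:
                dZ = np.sign(Z - Xb) / (B * d)
            dZ = dZ * g_grad(pre_z, Z)
            # decoder (W used as W^T) and encoder share W: sum both grads
            gW_dec = Y.T @ dZ  # (h, d)
            dY = (dZ @ W.T) * f_grad(pre_y, Y)  # (B, h)
            gW_enc = dY.T @ Xb  # (h, d)
            gW = gW_dec + gW_enc
            gb = dY.sum(axis=0)
            gb_out = dZ.sum(axis=0)

            vW = params.momentum * vW - params.learning_rate * gW
            vb = params.momentum * vb - params.learning_rate * gb
            vb_out = params.momentum * vb_out - params.learning_rate * gb_out
            W += vW
            b += vb
            b_out += vb_out

        _, Z_all = _forward(W, b, b_out, X, params.f_activation, params.g_activation)
        trace.append(_loss_value(X, Z_all, params.loss))

    return AEModel(W=W, b=b, b_out=b_out, params=params, loss_trace=trace)


def reconstruct(model: AEModel, features: np.ndarray) -> np.ndarray:
    """Decode-encode a matrix; output shape equals input shape."""
    X = np.asarray(features, dtype=np.float64)
    if X.shape[1] != model.W.shape[1]:
        raise ValueError(
            f"expected {model.W.shape[1]} columns, got {X.shape[1]}"
        )
    _, Z = _forward(
        model.W, model.b, model.b_out, X,
        model.params.f_activation, model.params.g_activation,
    )
    return Z


# ---------------------------------------------------------------------------
# T-split ranking
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GbdtParams:
    """Boosted-ensemble parameters for T-split feature ranking.

    For a multiclass target LightGBM grows one tree per class per
    boosting round, so K = n_rounds * n_classes trees contribute split
    counts.  ``min_child_samples`` is lowered from LightGBM's default
    20 so desk-scale toys still grow trees.
    """

    n_rounds: int = 100
    num_leaves: int = 31
    learning_rate: float = 0.1
    min_child_samples: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")


def fit_gbdt(features: np.ndarray, labels: np.ndarray, params: GbdtParams) -> lightgbm.LGBMClassifier:
    clf = lightgbm.LGBMClassifier(
        n_estimators=params.n_rounds,
        num_leaves=params.num_leaves,
        learning_rate=params.learning_rate,
        min_child_samples=params.min_child_samples,
        random_state=params.seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )
    clf.fit(np.asarray(features, dtype=np.float64), np.asarray(labels, dtype=object))
    return clf


def tsplit_rank(
    features: np.ndarray,
    labels: np.ndarray,
    params: GbdtParams,
    feature_ids: list[str] | None = None,
) -> FeatureRanking:
    """Rank features by total split count across the boosted ensemble."""
    labels = np.asarray(labels, dtype=object)
    if len(set(labels)) < 2:
        raise ValueError("tsplit_rank needs at least 2 classes")
    clf = fit_gbdt(features, labels, params)
    counts = clf.booster_.feature_importance(importance_type="split")
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(features.shape[1])]
    return FeatureRanking.from_scores(
        {g: float(c) for g, c in zip(feature_ids, counts)}, stage="tsplit"
    )


# ---------------------------------------------------------------------------
# the pass-2 pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ReboostBundle:
    """Pass-2 artifact: AE + ranking + curve + final model.

    The bundle keeps the autoencoder so new cells can be transformed
    into reconstructed-feature space before prediction.
    """

    ae_model: AEModel
    pass1_features: list[str]
    ranking: FeatureRanking
    curve: IFSCurve
    final_model: FittedModel

    def predict(self, ds: AccessibilityDataset) -> np.ndarray:
        Z = reconstruct(self.ae_model, ds.dense(self.pass1_features))
        recon = _reconstructed_dataset(ds, self.pass1_features, Z)
        return self.final_model.predict(recon)


def _reconstructed_dataset(
    ds: AccessibilityDataset, features: list[str], Z: np.ndarray
) -> AccessibilityDataset:
    return AccessibilityDataset(
        matrix=sp.csr_matrix(Z),
        cell_ids=list(ds.cell_ids),
        cell_types=list(ds.cell_types),
        gene_ids=list(features),
        kind="real",
    )


def reboost_pipeline(
    ds: AccessibilityDataset,
    pass1_features: list[str],
    ae: AEParams,
    gbdt: GbdtParams,
    classifier_spec: ClassifierSpec,
    folds: int = 10,
    smote: SmoteParams | None = None,
    seed: int = 0,
) -> tuple[IFSCurve, ReboostBundle]:
    """AE-reconstruct the pass-1 features, re-rank, re-run IFS at step 1."""
    X = ds.dense(pass1_features)
    model = train_autoencoder(X, dataclasses.replace(ae, seed=seed))
    Z = reconstruct(model, X)
    ranking = tsplit_rank(
        Z, ds.labels(), dataclasses.replace(gbdt, seed=seed), feature_ids=list(pass1_features)
    )
    recon = _reconstructed_dataset(ds, list(pass1_features), Z)
    curve = run_ifs(
        recon, ranking, classifier_spec, step=1, folds=folds, smote=smote, seed=seed
    )
    n_opt, _ = select_optimal(curve)
    final = fit_final(recon, ranking, n_opt, classifier_spec, smote=smote, seed=seed)
    bundle = ReboostBundle(
        ae_model=model,
        pass1_features=list(pass1_features),
        ranking=ranking,
        curve=curve,
        final_model=final,
    )
    return curve, bundle
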