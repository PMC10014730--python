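import numpy as np
import pytest

from atacml import (
    AEParams,
    GbdtParams,
    reboost_pipeline,
    reconstruct,
    train_autoencoder,
    tsplit_rank,
)
from atacml.autoencode import fit_gbdt
from atacml.evaluation import ClassifierSpec
from atacml.ifs import select_optimal

LINEAR = dict(f_activation="identity", g_activation="identity")


def count_split_nodes(booster):
    """Independent oracle: enumerate internal nodes in the model dump."""

    def walk(node):
        if "split_index" in node:
            return 1 + walk(node["left_child"]) + walk(node["right_child"])
        return 0

    dump = booster.dump_model()
    return sum(walk(t["tree_structure"]) for t in dump["tree_info"])


class TestAutoencoder:
    def test_full_width_linear_ae_reconstructs(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(64, 5))
        model = train_autoencoder(
            X, AEParams(embed_dim=5, epochs=400, learning_rate=0.05, seed=0, **LINEAR)
        )
        assert model.final_loss < 1e-3

    def test_rank_one_input_matches_pca_residual(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(64, 1)) @ rng.normal(size=(1, 6))
        model = train_autoencoder(
            X, AEParams(embed_dim=1, epochs=400, learning_rate=0.05, seed=1, **LINEAR)
        )
        Xc = X - X.mean(axis=0)
        sv = np.linalg.svd(Xc, compute_uv=False)
        pca_residual = float((sv[1:] ** 2).sum() / X.size)
        assert abs(model.final_loss - pca_residual) < 1e-3
        Z = reconstruct(model, X)
        assert np.allclose(Z, X, atol=1e-2)

    def test_same_seed_bit_identical_weights(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 8))
        params = AEParams(embed_dim=3, epochs=20, seed=5)
        m1 = train_autoencoder(X, params)
        m2 = train_autoencoder(X, params)
        assert np.array_equal(m1.W, m2.W)
        assert m1.loss_trace == m2.loss_trace

    def test_reconstruct_shape_and_recorded_loss(self):
        rng = np.random.default_rng(3)
        X = rng.random((30, 4))
        model = train_autoencoder(X, AEParams(embed_dim=2, epochs=30, seed=0))
        Z = reconstruct(model, X)
        assert Z.shape == X.shape
        assert np.all(np.isfinite(Z))
        recomputed = float(np.mean((Z - X) ** 2))
        assert recomputed == pytest.approx(model.final_loss, abs=1e-9)

    def test_loss_trace_converges(self):
        rng = np.random.default_rng(4)
        X = rng.random((50, 6))
        model = train_autoencoder(X, AEParams(embed_dim=3, epochs=100, seed=2))
        tail = model.loss_trace[-20:]
        assert tail[-1] <= tail[0] + 1e-6

    def test_decoder_weights_are_transposed_encoder(self):
        rng = np.random.default_rng(5)
        X = rng.random((20, 7))
        model = train_autoencoder(X, AEParams(embed_dim=3, epochs=5, seed=0))
        assert model.W.shape == (3, 7)
        assert model.b.shape == (3,) and model.b_out.shape == (7,)

    def test_non_finite_input_rejected(self):
        X = np.full((4, 2), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            train_autoencoder(X, AEParams(embed_dim=1))

    def test_width_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        model = train_autoencoder(rng.random((10, 3)), AEParams(embed_dim=2, epochs=2))
        with pytest.raises(ValueError, match="columns"):
            reconstruct(model, rng.random((5, 4)))


class TestTsplitRank:
    def test_unused_feature_scores_zero(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200).astype(str)
        informative = (y == "1").astype(float) + rng.normal(0, 0.1, 200)
        constant = np.zeros(200)
        F = np.column_stack([informative, constant])
        r = tsplit_rank(F, y, GbdtParams(n_rounds=5, seed=0), ["inf", "const"])
        scores = dict(zip(r.feature_ids, r.scores))
        assert scores["const"] == 0.0
        assert scores["inf"] > 0

    def test_single_stump_scores_one(self):
        y = np.repeat(["a", "b"], 50)
        F = np.column_stack([np.repeat([0.0, 1.0], 50), np.zeros(100)])
        r = tsplit_rank(
            F, y, GbdtParams(n_rounds=1, num_leaves=2, min_child_samples=1, seed=0),
            ["j", "other"],
        )
        scores = dict(zip(r.feature_ids, r.scores))
        assert scores["j"] == 1.0 and scores["other"] == 0.0

    def test_total_scores_equal_internal_node_count(self):
        rng = np.random.default_rng(7)
        n = 300
        y = rng.integers(0, 3, n).astype(str)
        F = rng.normal(size=(n, 5)) + (y[:, None] == "1") * 0.5
        params = GbdtParams(n_rounds=3, seed=3)
        r = tsplit_rank(F, y, params)
        booster = fit_gbdt(F, y, params).booster_
        assert r.scores.sum() == count_split_nodes(booster)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            tsplit_rank(np.zeros((10, 2)), np.array(["a"] * 10), GbdtParams())


class TestReboostPipeline:
    def test_separable_toy_keeps_perfect_mcc(self, separable):
        ds, truth = separable
        markers = truth.all_markers()
        curve, bundle = reboost_pipeline(
            ds, markers,
            AEParams(embed_dim=len(markers), epochs=150, seed=0),
            GbdtParams(n_rounds=20, min_child_samples=2, seed=0),
            ClassifierSpec("rf", {"n_estimators": 20}),
            folds=5, seed=3,
        )
        assert curve.step == 1
        assert len(curve) == len(markers)
        n_opt, rec = select_optimal(curve)
        assert rec.mcc == 1.0

    def test_bundle_predictions_reproducible(self, separable):
        ds, truth = separable
        markers = truth.all_markers()
        args = dict(
            ae=AEParams(embed_dim=4, epochs=50, seed=0),
            gbdt=GbdtParams(n_rounds=10, min_child_samples=2, seed=0),
            classifier_spec=ClassifierSpec("dt"),
            folds=5, seed=9,
        )
        _, b1 = reboost_pipeline(ds, markers, **args)
        _, b2 = reboost_pipeline(ds, markers, **args)
        assert np.array_equal(b1.predict(ds), b2.predict(ds))
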