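import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atacml import (
    ClassifierSpec,
    SmoteParams,
    cross_validated_performance,
    multiclass_mcc,
    overall_accuracy,
    per_class_accuracy,
    smote_balance,
)
from atacml.evaluation import stratified_fold_assignment

from conftest import make_dataset


def gorodkin_rk(pred, truth):
    """Independent closed form from confusion counts:
    (c*s - sum p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))."""
    classes = sorted(set(pred) | set(truth))
    idx = {c: i for i, c in enumerate(classes)}
    K = len(classes)
    C = np.zeros((K, K))
    for p, t in zip(pred, truth):
        C[idx[t], idx[p]] += 1
    s = C.sum()
    c = np.trace(C)
    p_k = C.sum(axis=0)
    t_k = C.sum(axis=1)
    num = c * s - p_k @ t_k
    den = np.sqrt((s**2 - p_k @ p_k) * (s**2 - t_k @ t_k))
    return 0.0 if den == 0 else num / den


class TestMulticlassMcc:
    @pytest.mark.parametrize(
        "pred, truth, expected",
        [
            (list("AABB"), list("AABB"), 1.0),
            (list("ABCABC"), list("ABCABC"), 1.0),
            (list("ABAB"), list("AABB"), 0.0),
            (list("AABCCB"), list("AABBCC"), 0.5),
        ],
    )
    def test_worked_examples(self, pred, truth, expected):
        assert multiclass_mcc(pred, truth) == pytest.approx(expected, abs=1e-12)

    def test_matches_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            k = int(rng.integers(2, 7))
            truth = [str(x) for x in rng.integers(0, k, n)]
            pred = [str(x) for x in rng.integers(0, k, n)]
            assert multiclass_mcc(pred, truth) == pytest.approx(
                gorodkin_rk(pred, truth), abs=1e-10
            )

    def test_binary_closed_form(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            tp, fp, fn, tn = rng.integers(0, 20, 4)
            pred = ["P"] * (tp + fp) + ["N"] * (fn + tn)
            truth = ["P"] * tp + ["N"] * fp + ["P"] * fn + ["N"] * tn
            den = np.sqrt(
                float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            )
            expected = 0.0 if den == 0 else (tp * tn - fp * fn) / den
            assert multiclass_mcc(pred, truth) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.sampled_from("ABCD"), st.sampled_from("ABCD")),
            min_size=1,
            max_size=40,
        )
    )
    def test_symmetry(self, pairs):
        pred = [p for p, _ in pairs]
        truth = [t for _, t in pairs]
        assert multiclass_mcc(pred, truth) == pytest.approx(
            multiclass_mcc(truth, pred), abs=1e-12
        )

    def test_zero_variance_convention(self):
        assert multiclass_mcc(["A", "A", "A"], ["A", "B", "A"]) == 0.0
        assert multiclass_mcc(["A", "B", "A"], ["A", "A", "A"]) == 0.0

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            multiclass_mcc(["A"], ["A", "B"])
        with pytest.raises(ValueError):
            multiclass_mcc([], [])


class TestAccuracies:
    def test_overall(self):
        assert overall_accuracy(list("ABCA"), list("ABCC")) == 0.75
        assert overall_accuracy(list("AB"), list("AB")) == 1.0
        assert overall_accuracy(list("BA"), list("AB")) == 0.0

    def test_per_class(self):
        acc = per_class_accuracy(list("ABB"), list("AAB"))
        assert acc == {"A": 0.5, "B": 1.0}

    def test_class_absent_from_truth_excluded(self):
        acc = per_class_accuracy(["A", "C"], ["A", "B"])
        assert set(acc) == {"A", "B"}

    def test_acc_is_weighted_mean_of_per_class(self):
        rng = np.random.default_rng(5)
        truth = [str(x) for x in rng.integers(0, 4, 200)]
        pred = [str(x) for x in rng.integers(0, 4, 200)]
        pca = per_class_accuracy(pred, truth)
        weights = {c: truth.count(c) / len(truth) for c in pca}
        assert overall_accuracy(pred, truth) == pytest.approx(
            sum(weights[c] * pca[c] for c in pca)
        )


def on_segment_of_class(row, X_cls, atol=1e-9):
    """True if row == x_i + u (x_j - x_i) for some pair of class rows."""
    for i in range(X_cls.shape[0]):
        d = row - X_cls[i]
        for j in range(X_cls.shape[0]):
            if i == j:
                continue
            seg = X_cls[j] - X_cls[i]
            nz = np.abs(seg) > atol
            if not nz.any():
                if np.allclose(d, 0, atol=atol):
                    return True
                continue
            u = d[nz][0] / seg[nz][0]
            if -atol <= u <= 1 + atol and np.allclose(d, u * seg, atol=atol):
                return True
    return False


class TestSmote:
    def test_balanced_input_returned_unchanged(self):
        ds = make_dataset(np.eye(4), ["A", "A", "B", "B"])
        out = smote_balance(ds, SmoteParams(k_neighbors=1, seed=0))
        assert out == ds

    def test_two_point_minority_interpolates_on_segment(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0], [0.5, 0], [0, 0.5]])
        labels = ["m", "m", "M", "M", "M", "M"]
        ds = make_dataset(X, labels, kind="fractional")
        out = smote_balance(ds, SmoteParams(k_neighbors=1, seed=2))
        new = out.matrix.toarray()[6:]
        assert new.shape == (2, 2)
        for row in new:
            assert row[0] == pytest.approx(row[1])  # on the (0,0)-(1,1) diagonal
            assert 0.0 <= row[0] <= 1.0

    def test_counts_equalized_and_rows_on_class_segments(self):
        rng = np.random.default_rng(8)
        sizes = {"A": 50, "B": 10, "C": 5}
        X, labels = [], []
        for cls, n in sizes.items():
            X.append((rng.random((n, 6)) < 0.5).astype(float))
            labels += [cls] * n
        X = np.vstack(X)
        ds = make_dataset(X, labels)
        out = smote_balance(ds, SmoteParams(k_neighbors=3, seed=4))
        from atacml import summarize_classes

        assert set(summarize_classes(out).counts.values()) == {50}
        # originals untouched, in order
        assert np.array_equal(out.matrix.toarray()[: len(labels)], X)
        y_out = out.labels()
        for i in range(len(labels), out.n_cells):
            cls = y_out[i]
            X_cls = X[np.array(labels) == cls]
            assert on_segment_of_class(out.matrix.toarray()[i], X_cls)

    def test_singleton_class_rejected(self):
        ds = make_dataset(np.eye(3), ["A", "A", "B"])
        with pytest.raises(ValueError, match="single sample"):
            smote_balance(ds, SmoteParams(k_neighbors=1, seed=0))

    def test_deterministic(self):
        ds = make_dataset(np.eye(6), ["A"] * 4 + ["B"] * 2)
        a = smote_balance(ds, SmoteParams(k_neighbors=1, seed=3))
        b = smote_balance(ds, SmoteParams(k_neighbors=1, seed=3))
        assert a == b


class TestCrossValidation:
    def test_fold_assignment_stratified_and_tiny_classes(self):
        labels = ["A"] * 20 + ["B"] * 3
        f = stratified_fold_assignment(labels, 10, seed=0)
        assert set(f[:20]) == set(range(10))  # A appears in every fold twice
        assert len(set(f[20:])) == 3  # B contributes to 3 distinct folds

    def test_separable_data_scores_perfectly(self, separable):
        ds, truth = separable
        rec = cross_validated_performance(
            ds, truth.all_markers(), ClassifierSpec("rf", {"n_estimators": 30}),
            folds=10, seed=1,
        )
        assert rec.mcc == 1.0 and rec.acc == 1.0
        assert all(v == 1.0 for v in rec.per_class_accuracy.values())

    def test_uninformative_feature_gives_zero_mcc(self, separable):
        ds, _ = separable
        zero_col = [g for g in ds.gene_ids
                    if ds.matrix[:, ds.gene_ids.index(g)].nnz == 0][0]
        rec = cross_validated_performance(
            ds, [zero_col], ClassifierSpec("dt"), folds=5, seed=0
        )
        assert rec.mcc == 0.0

    def test_deterministic_given_seed(self, benchmark):
        ds, _ = benchmark
        features = ds.gene_ids[:30]
        spec = ClassifierSpec("rf", {"n_estimators": 20})
        r1 = cross_validated_performance(ds, features, spec, folds=10, seed=7)
        r2 = cross_validated_performance(ds, features, spec, folds=10, seed=7)
        assert r1 == r2

    def test_unknown_feature_and_classifier_rejected(self, separable):
        ds, _ = separable
        with pytest.raises(KeyError):
            cross_validated_performance(ds, ["nope"], ClassifierSpec("dt"))
        with pytest.raises(ValueError, match="unknown classifier"):
            cross_validated_performance(ds, ds.gene_ids[:2], ClassifierSpec("svm"))
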