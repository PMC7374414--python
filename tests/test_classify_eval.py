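import numpy as np
import pytest

from pcg_chd.classify_eval import (
    FUSED_DIM,
    SvmSpec,
    compute_metrics,
    cross_validate,
    fuse,
    train_svm,
)


class TestFuse:
    def test_concatenation_order_mfcc_then_ltp(self):
        out = fuse(np.ones(13), np.full(20, 2.0))
        assert out.shape == (FUSED_DIM,)
        np.testing.assert_array_equal(out[:13], 1.0)
        np.testing.assert_array_equal(out[13:], 2.0)

    def test_wrong_lengths_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.ones(12), np.ones(20))
        with pytest.raises(ValueError):
            fuse(np.ones(13), np.ones(21))


class TestTrainSvm:
    def test_linear_kernel_separates_separable_toy_set(self):
        X = np.vstack([np.random.default_rng(0).normal(-3, 0.3, (20, 2)),
                       np.random.default_rng(1).normal(3, 0.3, (20, 2))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        model = train_svm(X, y, SvmSpec(kernel="linear"))
        assert (model.predict(X) == y).all()

    def test_gaussian_solves_xor_where_linear_cannot(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        rbf = train_svm(X, y, SvmSpec(kernel="gaussian", kernel_scale=0.3, standardize=False))
        assert (rbf.predict(X) == y).all()
        lin = train_svm(X, y, SvmSpec(kernel="linear", standardize=False))
        assert (lin.predict(X) != y).any()

    def test_standardization_zscores_training_features(self):
        rng = np.random.default_rng(2)
        X = rng.normal(10, 5, (50, 3))
        y = rng.integers(0, 2, 50)
        model = train_svm(X, y, SvmSpec(kernel="linear"))
        Z = model.named_steps["scale"].transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-9)

    def test_single_class_and_nan_features_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((5, 2)), np.zeros(5), SvmSpec())
        X = np.zeros((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_svm(X, [0, 0, 1, 1], SvmSpec())

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SvmSpec(kernel="sigmoid")
        with pytest.raises(ValueError):
            SvmSpec(kernel_scale=-1.0)
        with pytest.raises(ValueError):
            SvmSpec(box_constraint=0.0)


class TestComputeMetrics:
    def test_binary_sensitivity_specificity_accuracy(self):
        # rows actual (negative first), columns predicted
        conf = np.array([[90, 10], [2, 98]])
        m = compute_metrics(conf, positive_index=1)
        assert np.isclose(m["sensitivity"], 98.0)
        assert np.isclose(m["specificity"], 90.0)
        assert np.isclose(m["accuracy"], 94.0)
        assert np.isclose(m["error"], 6.0)
        assert np.isclose(m["ppv"], 100 * 98 / 108)
        assert np.isclose(m["npv"], 100 * 90 / 92)

    def test_perfect_confusion_gives_all_hundreds(self):
        m = compute_metrics(np.diag([10, 20, 30]))
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert np.isclose(m[name], 100.0)
        assert m["error"] == 0.0

    def test_zero_denominator_yields_nan_marker(self):
        m = compute_metrics(np.array([[5, 0], [0, 0]]), positive_index=1)
        assert np.isnan(m["sensitivity"])
        assert np.isclose(m["accuracy"], 100.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([[1, -1], [0, 2]]))

    def test_identities_on_random_confusions(self, rng):
        for _ in range(200):
            k = rng.integers(2, 5)
            conf = rng.integers(0, 50, (k, k)).astype(float)
            if conf.sum() == 0:
                continue
            m = compute_metrics(conf)
            assert np.isclose(m["accuracy"], 100 * np.trace(conf) / conf.sum())
            assert np.isclose(m["accuracy"] + m["error"], 100.0)


class TestCrossValidate:
    def _separable(self, n=60, k=3, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(5 * i, 0.2, (n // k, 4)) for i in range(k)])
        y = np.repeat([f"c{i}" for i in range(k)], n // k)
        return X, y

    def test_separable_features_reach_full_accuracy(self):
        X, y = self._separable()
        rep = cross_validate(X, y, SvmSpec(kernel="linear"), k=5, repeats=3, seed=0)
        assert rep.metrics["accuracy"] == 100.0
        assert rep.metrics["error"] == 0.0

    def test_confusion_rows_sum_to_class_counts(self):
        X, y = self._separable()
        rep = cross_validate(X, y, SvmSpec(kernel="cubic"), k=5, repeats=2, seed=1)
        np.testing.assert_allclose(rep.confusion.sum(axis=1), 20)

    def test_same_seed_reproduces_report(self):
        X, y = self._separable(seed=3)
        a = cross_validate(X, y, SvmSpec(), k=4, repeats=3, seed=9)
        b = cross_validate(X, y, SvmSpec(), k=4, repeats=3, seed=9)
        assert a.per_repeat_accuracies == b.per_repeat_accuracies
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_fold_count_reduced_when_class_too_small(self):
        X, y = self._separable(n=12, k=3)
        with pytest.warns(UserWarning, match="reducing folds"):
            rep = cross_validate(X, y, SvmSpec(), k=10, repeats=1, seed=0)
        assert rep.n_folds == 4

    def test_binary_positive_class_defaults_to_abnormal(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(4, 1, (30, 3))])
        y = np.array(["normal"] * 30 + ["abnormal"] * 30)
        rep = cross_validate(X, y, SvmSpec(kernel="linear"), k=5, repeats=2, seed=0)
        assert rep.classes == ["abnormal", "normal"]
        assert rep.metrics["sensitivity"] > 90

    def test_invalid_fold_counts_rejected(self):
        X, y = self._separable()
        with pytest.raises(ValueError):
            cross_validate(X, y, SvmSpec(), k=1)
        with pytest.raises(ValueError):
            cross_validate(X, y, SvmSpec(), k=100)
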