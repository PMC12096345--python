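"""CNN, baselines, metrics — unit tests and seeded regression properties."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from conftest import blob_dataset
from hsfkit.models import (
    BaselineSpec,
    CNNClassifier,
    build_cnn,
    candidate_grid,
    evaluate,
    fit_baseline,
    report_from_predictions,
    train_cnn,
)
from hsfkit.models.baselines import _make_estimator


# --------------------------------------------------------------------- spec

class TestBuildCNN:
    def test_output_width(self):
        spec = build_cnn(86)
        assert spec.output_width == 86

    def test_exactly_three_conv_stages(self):
        spec = build_cnn(5)
        assert len(spec.conv_stages) == 3
        with pytest.raises(ValueError, match="3 conv stages"):
            build_cnn(5, conv_stages=((8, 3, 2), (16, 3, 2)))

    def test_min_classes(self):
        with pytest.raises(ValueError, match="n_classes"):
            build_cnn(1)

    def test_probabilities_sum_to_one(self):
        model = CNNClassifier(build_cnn(7, conv_stages=((4, 3, 2), (4, 3, 2), (4, 3, 2)),
                                        dense_widths=(16,)))
        x = np.random.default_rng(0).random((5, 66, 66, 1)).astype(np.float32)
        probs = model.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)


# ----------------------------------------------------------------- training

SMALL_STAGES = ((4, 3, 2), (8, 3, 2), (8, 3, 2))


class TestTrainCNN:
    def test_separable_toy_reaches_full_train_accuracy(self):
        x, y = blob_dataset(n_per_class=10, n_classes=3, seed=1)
        # oracle: nearest-centroid proves the classes are separable
        centroids = np.stack([x[y == k].mean(axis=0) for k in range(3)])
        d = ((x[:, None] - centroids[None]) ** 2).sum(axis=(2, 3, 4))
        assert np.all(d.argmin(axis=1) == y)
        spec = build_cnn(3, conv_stages=SMALL_STAGES, dense_widths=(32,),
                         epochs=30, seed=0)
        model, trace = train_cnn(spec, x, y)
        assert np.mean(model.predict(x) == y) == 1.0

    def test_single_class_degenerate_set(self):
        x, y = blob_dataset(n_per_class=6, n_classes=1, seed=2)
        spec = build_cnn(2, conv_stages=SMALL_STAGES, dense_widths=(8,),
                         epochs=5, seed=0)
        model, _ = train_cnn(spec, x, np.zeros(len(x), dtype=int))
        assert np.all(model.predict(x) == 0)

    def test_seeded_determinism(self):
        x, y = blob_dataset(n_per_class=4, n_classes=2, seed=3)
        spec = build_cnn(2, conv_stages=SMALL_STAGES, dense_widths=(8,),
                         epochs=3, seed=7)
        m1, _ = train_cnn(spec, x, y)
        m2, _ = train_cnn(spec, x, y)
        assert m1.params_hash() == m2.params_hash()

    def test_loss_trace_decreases_smoothed(self):
        x, y = blob_dataset(n_per_class=8, n_classes=3, seed=4)
        spec = build_cnn(3, conv_stages=SMALL_STAGES, dense_widths=(16,),
                         epochs=12, seed=0)
        _, trace = train_cnn(spec, x, y)
        smooth = np.convolve(trace, np.ones(3) / 3, mode="valid")
        assert smooth[-1] < smooth[0]
        assert np.all(np.diff(smooth) <= 0.05 * smooth[0])  # near-monotone

    def test_shape_mismatch_rejected(self):
        spec = build_cnn(2, conv_stages=SMALL_STAGES, dense_widths=(8,), epochs=1)
        model = CNNClassifier(spec)
        with pytest.raises(ValueError, match="input shape"):
            model.fit(np.zeros((4, 30, 30, 1), dtype=np.float32), np.zeros(4, dtype=int))

    def test_empty_training_set_rejected(self):
        spec = build_cnn(2, conv_stages=SMALL_STAGES, dense_widths=(8,), epochs=1)
        with pytest.raises(ValueError, match="empty"):
            CNNClassifier(spec).fit(np.zeros((0, 66, 66, 1), dtype=np.float32),
                                    np.zeros(0, dtype=int))

    def test_save_load_round_trip(self, tmp_path):
        x, y = blob_dataset(n_per_class=4, n_classes=2, seed=5)
        spec = build_cnn(2, conv_stages=SMALL_STAGES, dense_widths=(8,),
                         epochs=2, seed=0)
        model, _ = train_cnn(spec, x, y)
        model.save(tmp_path / "model.npz")
        back = CNNClassifier.load(tmp_path / "model.npz")
        np.testing.assert_allclose(back.predict_proba(x), model.predict_proba(x))


class TestGradients:
    def test_backprop_matches_numeric_gradient(self):
        """Central-difference oracle on a handful of parameters."""
        spec = build_cnn(3, conv_stages=((2, 3, 2), (2, 3, 2), (2, 3, 2)),
                         dense_widths=(6,), seed=0)
        model = CNNClassifier(spec)
        model.params = {k: v.astype(np.float64) for k, v in model.params.items()}
        rng = np.random.default_rng(1)
        x = rng.random((2, 66, 66, 1))
        y = np.array([0, 2])

        def loss():
            logits = model._forward(x)
            z = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            return -np.mean(np.log(p[np.arange(2), y]))

        cache: list = []
        logits = model._forward(x, cache)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        dlogits = p.copy()
        dlogits[np.arange(2), y] -= 1.0
        grads = model._backward(cache, dlogits / 2)

        eps = 1e-6
        for name in ("convW0", "convW2", "denseW0", "denseW1", "denseb1"):
            flat = model.params[name].ravel()
            for idx in rng.choice(flat.size, size=3, replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = grads[name].ravel()[idx]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7), name


# ---------------------------------------------------------------- baselines

class TestBaselineGrid:
    def test_svm_grid_size(self):
        # combinatorial oracle: 6 strengths x 4 kernels x (4 PCA + none)
        spec = BaselineSpec("svm")
        assert len(candidate_grid(spec)) == 6 * 4 * (4 + 1) == 120

    def test_lr_grid_size(self):
        assert len(candidate_grid(BaselineSpec("lr"))) == 6 * 5

    def test_rf_grid_size(self):
        assert len(candidate_grid(BaselineSpec("rf"))) == 5

    def test_strength_zero_is_penalty_free(self):
        lr = _make_estimator(BaselineSpec("lr"), {"strength": 0.0, "pca": None})
        assert lr.named_steps["ovr"].estimator.penalty is None
        svm = _make_estimator(BaselineSpec("svm"),
                              {"strength": 0.0, "kernel": "rbf", "pca": None})
        assert svm.named_steps["ovr"].estimator.C == 1e6

    def test_strength_maps_to_inverse_c(self):
        lr = _make_estimator(BaselineSpec("lr"), {"strength": 0.5, "pca": None})
        assert lr.named_steps["ovr"].estimator.C == pytest.approx(2.0)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="algorithm"):
            BaselineSpec("xgboost")


class TestFitBaseline:
    @pytest.mark.parametrize("algorithm", ["lr", "rf", "svm"])
    def test_separable_toy_perfect_accuracy(self, algorithm):
        x, y = blob_dataset(n_per_class=12, n_classes=3, seed=6)
        xtr, ytr = x[:27], y[:27]
        xte, yte = x[27:], y[27:]
        spec = BaselineSpec(algorithm,
                            regularization_strengths=(0.0, 0.2),
                            kernels=("linear", "rbf"),
                            pca_components=(5,),
                            n_estimators=50, seed=0)
        model = fit_baseline(spec, xtr.reshape(27, -1), ytr)
        assert np.mean(model.predict(xte.reshape(len(xte), -1)) == yte) == 1.0

    def test_returns_chosen_hyperparameters(self):
        x, y = blob_dataset(n_per_class=8, n_classes=2, seed=7)
        spec = BaselineSpec("lr", regularization_strengths=(0.2,),
                            pca_components=(3,), include_no_pca=False, seed=0)
        model = fit_baseline(spec, x.reshape(len(x), -1), y)
        assert model.best_params == {"strength": 0.2, "pca": 3}
        assert 0.0 <= model.cv_score <= 1.0

    def test_degenerate_fold_skipped_with_warning(self):
        x, y = blob_dataset(n_per_class=9, n_classes=2, seed=8)
        y = y.copy()
        y[np.flatnonzero(y == 1)[1:]] = 0  # leave one single-example class
        spec = BaselineSpec("lr", regularization_strengths=(0.2,),
                            pca_components=(2,), include_no_pca=False,
                            cv_folds=3, seed=0)
        with pytest.warns(UserWarning, match="fold"):
            fit_baseline(spec, x.reshape(len(x), -1), y)

    def test_oversized_pca_skipped(self):
        x, y = blob_dataset(n_per_class=4, n_classes=2, seed=9)
        spec = BaselineSpec("lr", regularization_strengths=(0.2,),
                            pca_components=(4, 5000), include_no_pca=False, seed=0)
        with pytest.warns(UserWarning, match="PCA width"):
            model = fit_baseline(spec, x.reshape(len(x), -1), y)
        assert model.best_params["pca"] == 4

    def test_probabilities_normalized(self):
        x, y = blob_dataset(n_per_class=6, n_classes=3, seed=10)
        spec = BaselineSpec("svm", regularization_strengths=(0.2,), kernels=("rbf",),
                            pca_components=(3,), include_no_pca=False, seed=0)
        model = fit_baseline(spec, x.reshape(len(x), -1), y)
        probs = model.predict_proba(x.reshape(len(x), -1))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)

    def test_all_zero_input_predicts_valid_distribution(self):
        x, y = blob_dataset(n_per_class=6, n_classes=2, seed=11)
        spec = BaselineSpec("lr", regularization_strengths=(0.2,),
                            pca_components=(2,), include_no_pca=False, seed=0)
        model = fit_baseline(spec, x.reshape(len(x), -1), y)
        probs = model.predict_proba(np.zeros((1, 66 * 66)))
        assert probs.shape[1] >= 2
        assert probs.sum() == pytest.approx(1.0)


# ------------------------------------------------------------------ metrics

class TestMetrics:
    def test_all_correct(self):
        rep = report_from_predictions([0, 1, 2, 1], [0, 1, 2, 1])
        assert rep.accuracy == 100.0
        assert rep.macro_f1 == 100.0
        assert rep.misclassifications == ()

    def test_three_errors_of_344(self):
        y_true = [0] * 344
        y_pred = [0] * 341 + [1] * 3
        rep = report_from_predictions(y_true, y_pred, classes=[0, 1])
        assert round(rep.accuracy, 1) == 99.1

    def test_two_class_confusion_macro_oracle(self):
        """Hand-check oracle on confusion [[8, 2], [1, 9]]."""
        y_true = [0] * 10 + [1] * 10
        y_pred = [0] * 8 + [1] * 2 + [0] * 1 + [1] * 9
        rep = report_from_predictions(y_true, y_pred)
        np.testing.assert_array_equal(rep.confusion, [[8, 2], [1, 9]])
        # direct formula evaluation, independent of the implementation
        p0, p1 = 8 / 9, 9 / 11
        r0, r1 = 8 / 10, 9 / 10
        assert rep.macro_precision == pytest.approx(100 * (p0 + p1) / 2)
        assert rep.macro_recall == pytest.approx(100 * (r0 + r1) / 2)
        f0 = 2 * p0 * r0 / (p0 + r0)
        f1 = 2 * p1 * r1 / (p1 + r1)
        assert rep.macro_f1 == pytest.approx(100 * (f0 + f1) / 2)

    def test_confusion_marginals_conserve_counts(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 100)
        y_pred = rng.integers(0, 4, 100)
        rep = report_from_predictions(y_true, y_pred, classes=[0, 1, 2, 3])
        np.testing.assert_array_equal(rep.confusion.sum(axis=1),
                                      np.bincount(y_true, minlength=4))
        assert rep.n_test == 100

    def test_brute_force_oracle_random_matrices(self):
        """Per-class loops recompute every metric from scratch."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(10, 60))
            y_true = rng.integers(0, k, n)
            y_pred = rng.integers(0, k, n)
            rep = report_from_predictions(y_true, y_pred, classes=list(range(k)))
            assert rep.accuracy == pytest.approx(100 * np.mean(y_true == y_pred))
            ps, rs, fs = [], [], []
            for c in range(k):
                if not np.any(y_true == c):
                    continue
                tp = np.sum((y_true == c) & (y_pred == c))
                fp = np.sum((y_true != c) & (y_pred == c))
                fn = np.sum((y_true == c) & (y_pred != c))
                p = tp / (tp + fp) if tp + fp else 0.0
                r = tp / (tp + fn) if tp + fn else 0.0
                ps.append(p)
                rs.append(r)
                fs.append(2 * p * r / (p + r) if p + r else 0.0)
            assert rep.macro_precision == pytest.approx(100 * np.mean(ps))
            assert rep.macro_recall == pytest.approx(100 * np.mean(rs))
            assert rep.macro_f1 == pytest.approx(100 * np.mean(fs))

    def test_unknown_test_label_rejected(self):
        class Stub:
            def predict_proba(self, x):
                return np.full((len(x), 3), 1 / 3)

        with pytest.raises(ValueError, match="class range"):
            evaluate(Stub(), np.zeros((2, 4)), np.array([0, 7]))

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            report_from_predictions([], [])

    def test_misclassifications_ranked(self):
        y_true = ["a", "a", "a", "b", "b"]
        y_pred = ["b", "b", "b", "a", "b"]
        rep = report_from_predictions(y_true, y_pred)
        assert rep.misclassifications[0] == ("a", "b", 3)
        assert rep.misclassifications[1] == ("b", "a", 1)


# ----------------------------------------------- seeded library regressions

class TestDefaultLibraryRegression:
    def test_cnn_accuracy_floor(self, trained_cnn):
        assert trained_cnn["report"].accuracy >= 95.0

    def test_svm_accuracy_floor(self, default_run):
        x, y = default_run["x"], default_run["y"]
        split = default_run["split"]
        tr, te = list(split.train_ids), list(split.test_ids)
        spec = BaselineSpec("svm", regularization_strengths=(0.0,), kernels=("rbf",),
                            pca_components=(50,), include_no_pca=False, seed=17)
        model = fit_baseline(spec, x[tr].reshape(len(tr), -1), y[tr])
        rep = evaluate(model, x[te].reshape(len(te), -1), y[te],
                       classes=default_run["classes"])
        assert rep.accuracy >= 95.0

    def test_mixtures_not_confused_with_components(self, default_run, trained_cnn):
        """Mixture classes must not collapse onto either pure component."""
        classes = default_run["classes"]
        rep = trained_cnn["report"]
        idx = {c: k for k, c in enumerate(classes)}
        for mix, parts in [
            ("bromazolam+metonitazene", ("bromazolam:low", "metonitazene")),
            ("fentanyl+xylazine", ("fentanyl", "xylazine")),
            ("heroin+etonitazene", ("heroin", "etonitazene")),
        ]:
            row = rep.confusion[idx[mix]]
            total = row.sum()
            if total == 0:
                continue
            confused = sum(row[idx[p]] for p in parts)
            assert confused / total <= 0.2, mix

    def test_alprazolam_low_vs_medium_separated(self, default_run, trained_cnn):
        """0.1 vs 0.2 mg/mL held-out discrimination >= 90% pairwise."""
        classes = default_run["classes"]
        y = default_run["y"]
        te = trained_cnn["test_ids"]
        model = trained_cnn["model"]
        lo, mid = classes.index("alprazolam:low"), classes.index("alprazolam:medium")
        mask = np.isin(y[te], [lo, mid])
        assert mask.sum() >= 4  # both classes appear in the held-out fifth
        x_pair = default_run["x"][te][mask]
        y_pair = y[te][mask]
        pred = model.predict(x_pair)
        # pairwise: restrict scores to the two candidate classes
        probs = model.predict_proba(x_pair)[:, [lo, mid]]
        pair_pred = np.where(probs[:, 0] >= probs[:, 1], lo, mid)
        assert np.mean(pair_pred == y_pair) >= 0.9
        assert np.mean(pred == y_pair) >= 0.9

    def test_held_out_alprazolam_low_top1(self, default_run, trained_cnn):
        classes = default_run["classes"]
        y = default_run["y"]
        te = trained_cnn["test_ids"]
        lo = classes.index("alprazolam:low")
        mask = y[te] == lo
        if not mask.any():
            pytest.skip("no held-out alprazolam:low at this seed")
        probs = trained_cnn["model"].predict_proba(default_run["x"][te][mask])
        assert np.all(probs.argmax(axis=1) == lo)
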