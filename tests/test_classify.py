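"""SVM kernels, training, LOSO cross-validation, metrics and reconstruction."""

import numpy as np
import pandas as pd
import pytest

from drowsekit.classify import (
    ConfusionMatrix,
    SVMModel,
    TrainingError,
    confusion,
    default_grid,
    grid_optimize,
    kernel_eval,
    loso_crossval,
    metrics,
    reconstruct_confusion,
    train_svm,
)


class TestKernelEval:
    def test_linear_is_dot_product(self):
        assert kernel_eval("linear", [1, 2], [3, 4]) == 11.0

    def test_rbf_at_zero_distance_is_one(self):
        assert kernel_eval("rbf", [1.0, 2.0], [1.0, 2.0], g=0.7) == 1.0

    def test_rbf_at_distance_sq_2g2_is_inv_e(self):
        g = 1.5
        x = np.zeros(2)
        xp = np.array([g * np.sqrt(2.0), 0.0])  # ||x - x'||^2 = 2 g^2
        assert kernel_eval("rbf", x, xp, g=g) == pytest.approx(np.exp(-1.0))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            kernel_eval("linear", [1, 2], [1, 2, 3])

    def test_rbf_needs_positive_g(self):
        with pytest.raises(ValueError):
            kernel_eval("rbf", [1.0], [2.0], g=0.0)


def blobs(rng, n_per=15, gap=4.0, d=3):
    X = np.vstack(
        [rng.normal(0, 1, (n_per, d)), rng.normal(gap, 1, (n_per, d))]
    )
    y = np.array([-1] * n_per + [1] * n_per)
    return X, y


class TestTrainPredict:
    def test_two_separable_points_linear(self):
        model = train_svm([[0.0], [1.0]], [-1, 1], kernel="linear", C=1.0)
        np.testing.assert_array_equal(model.predict([[0.0], [1.0]]), [-1, 1])

    def test_single_class_is_training_error(self):
        with pytest.raises(TrainingError):
            train_svm([[0.0], [1.0]], [1, 1], kernel="linear")

    def test_separated_mp_trains_above_95pct(self, default_windows):
        w = default_windows[default_windows["label"] != 0]
        model = train_svm(
            w[["mp"]].to_numpy(), w["label"].to_numpy(), kernel="rbf", C=1.0, g=1.0
        )
        acc = (model.predict(w[["mp"]].to_numpy()) == w["label"].to_numpy()).mean()
        assert acc >= 0.95

    def test_zero_decision_value_maps_to_drowsy(self):
        # hand-built linear model whose decision value at x=0 is exactly 0
        model = SVMModel(
            kernel="linear",
            C=1.0,
            g=None,
            scale_mean=np.zeros(1),
            scale_std=np.ones(1),
            support_vectors_=np.array([[1.0], [-1.0]]),
            dual_coef_=np.array([1.0, -1.0]),
            intercept_=0.0,
        )
        assert model.decision_function([[0.0]])[0] == 0.0
        assert model.predict([[0.0]])[0] == 1

    def test_scaling_lives_inside_the_model(self, rng):
        X, y = blobs(rng)
        model = train_svm(X, y, kernel="rbf", C=1.0, g=1.0, scale=True)
        # raw features go in; the model applies its stored affine transform
        assert (model.predict(X) == y).mean() == 1.0
        assert model.scale_std.shape == (3,)

    @pytest.mark.parametrize("kernel,g", [("linear", None), ("rbf", 0.8)])
    def test_decision_function_matches_kernel_sum_oracle(self, rng, kernel, g):
        X, y = blobs(rng, gap=2.0)
        model = train_svm(X, y, kernel=kernel, C=1.0, g=g)
        assert len(model.support_vectors_) <= 50
        Z = model.transform(X)
        manual = np.array(
            [
                sum(
                    a * kernel_eval(kernel, z, sv, g=g)
                    for a, sv in zip(model.dual_coef_, model.support_vectors_)
                )
                + model.intercept_
                for z in Z
            ]
        )
        np.testing.assert_allclose(model.decision_function(X), manual, atol=1e-8)

    def test_json_round_trip_is_bit_reproducible(self, rng, tmp_path):
        X, y = blobs(rng)
        model = train_svm(X, y, kernel="rbf", C=2.0, g=0.5)
        model.to_json(tmp_path / "m.json")
        back = SVMModel.from_json(tmp_path / "m.json")
        np.testing.assert_array_equal(back.predict(X), model.predict(X))
        np.testing.assert_allclose(
            back.decision_function(X), model.decision_function(X), rtol=1e-12
        )

    def test_dimension_mismatch_rejected(self, rng):
        X, y = blobs(rng)
        model = train_svm(X, y, kernel="linear")
        with pytest.raises(ValueError, match="features"):
            model.predict([[1.0, 2.0]])


def separable_windows(rng, n_subjects=4, n_windows=12):
    """MP alone fully determines the label via a threshold at 100."""
    rows = []
    for s in range(n_subjects):
        for i in range(n_windows):
            drowsy = i % 2 == 0
            mp = rng.uniform(150, 200) if drowsy else rng.uniform(30, 60)
            rows.append(
                {
                    "subject": f"S{s:02d}",
                    "window_index": i,
                    "rbp_theta": rng.uniform(10, 20),
                    "rbp_alpha": rng.uniform(30, 50),
                    "rbp_beta": rng.uniform(30, 50),
                    "mp": mp,
                    "label": 1 if drowsy else -1,
                }
            )
    return pd.DataFrame(rows)


class TestLoso:
    def test_one_round_per_subject_and_pooled_counts(self, default_windows):
        res = loso_crossval(default_windows, ["mp"], kernel="rbf", C=1.0, g=1.0)
        assert len(res.round_accuracies) == 6
        assert res.pooled.total == res.n_windows == 266

    def test_separable_instance_is_perfect(self, rng):
        w = separable_windows(rng)
        res = loso_crossval(w, ["mp"], kernel="linear", C=1.0)
        assert res.accuracy == 100.0

    def test_fewer_than_two_subjects_rejected(self, rng):
        w = separable_windows(rng, n_subjects=1)
        with pytest.raises(TrainingError, match="2 subjects"):
            loso_crossval(w, ["mp"])

    def test_single_class_training_fold_reported(self, rng):
        w = separable_windows(rng, n_subjects=2)
        w.loc[w["subject"] == "S00", "label"] = 1  # S00 all drowsy
        res = loso_crossval(w, ["mp"], kernel="linear", C=1.0)
        assert "S01" in res.fold_errors  # training on S00 alone cannot work
        assert "S00" in res.round_accuracies


class TestGridOptimize:
    def test_single_point_grid_returned(self, rng):
        w = separable_windows(rng)
        res = grid_optimize(w, ["mp"], "rbf", C_grid=[2.0], g_grid=[0.5])
        assert (res.C, res.g) == (2.0, 0.5)

    def test_ties_break_to_smallest_c_then_g(self, rng):
        # every grid point solves the separable instance -> tie-minimal wins
        w = separable_windows(rng)
        res = grid_optimize(w, ["mp"], "rbf", C_grid=[5.0, 1.0, 3.0], g_grid=[2.0, 0.5])
        assert res.accuracy == 100.0
        assert (res.C, res.g) == (1.0, 0.5)

    def test_linear_kernel_ignores_g_grid(self, rng):
        w = separable_windows(rng)
        res = grid_optimize(w, ["mp"], "linear", C_grid=[1.0], g_grid=[7.0])
        assert res.g is None

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            grid_optimize(separable_windows(rng), ["mp"], "rbf", C_grid=[])

    def test_best_point_dominates_spot_checks(self, default_windows, rng):
        grid = default_grid(4)
        best = grid_optimize(default_windows, ["mp"], "rbf", C_grid=grid, g_grid=grid)
        for C in rng.choice(grid, 2, replace=False):
            for g in rng.choice(grid, 2, replace=False):
                other = loso_crossval(default_windows, ["mp"], "rbf", C, g)
                assert best.accuracy >= other.accuracy


class TestMetrics:
    def test_hybrid_linear_worked_example(self):
        # TP=191 FN=7 TN=65 FP=3 -> Acc 96.24, Sens 96.46, Spec 95.59
        acc, sens, spec = metrics(ConfusionMatrix(tp=191, tn=65, fp=3, fn=7))
        assert (round(acc, 2), round(sens, 2), round(spec, 2)) == (96.24, 96.46, 95.59)

    def test_all_correct(self):
        assert metrics(ConfusionMatrix(10, 20, 0, 0)) == (100.0, 100.0, 100.0)

    def test_balanced_errors_give_50_50(self):
        _, sens, spec = metrics(ConfusionMatrix(tp=5, fn=5, tn=8, fp=8))
        assert (sens, spec) == (50.0, 50.0)

    def test_constant_drowsy_classifier_on_study_counts(self):
        # predict +1 everywhere on 198 positives / 68 negatives
        y_true = np.array([1] * 198 + [-1] * 68)
        cm = confusion(y_true, np.ones_like(y_true))
        acc, sens, spec = metrics(cm)
        assert sens == 100.0 and spec == 0.0
        assert acc == pytest.approx(100 * 198 / 266)

    def test_missing_class_warns_and_gives_nan(self):
        with pytest.warns(UserWarning):
            _, sens, spec = metrics(ConfusionMatrix(tp=5, tn=0, fp=0, fn=1))
        assert np.isnan(spec) and not np.isnan(sens)


class TestReconstructConfusion:
    @pytest.mark.parametrize(
        "sens,spec,tp,tn",
        [
            (96.46, 95.59, 191, 65),
            (95.45, 45.59, 189, 31),
            (100.0, 0.0, 198, 0),
        ],
    )
    def test_printed_rates_invert_to_counts(self, sens, spec, tp, tn):
        cm = reconstruct_confusion(sens, spec, positives=198, negatives=68)
        assert (cm.tp, cm.tn) == (tp, tn)
        assert (cm.tp + cm.fn, cm.tn + cm.fp) == (198, 68)

    def test_round_trips_through_metrics(self, rng):
        for _ in range(50):
            P, N = rng.integers(10, 300, 2)
            tp, tn = rng.integers(0, P + 1), rng.integers(0, N + 1)
            sens, spec = round(100 * tp / P, 2), round(100 * tn / N, 2)
            cm = reconstruct_confusion(sens, spec, P, N)
            _, s2, p2 = metrics(cm)
            assert round(s2, 2) == sens and round(p2, 2) == spec

    def test_inconsistent_rates_warn(self):
        with pytest.warns(UserWarning, match="pre-image"):
            reconstruct_confusion(50.2, 50.0, positives=3, negatives=10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_confusion(120.0, 50.0, 10, 10)
        with pytest.raises(ValueError):
            reconstruct_confusion(50.0, 50.0, 0, 10)
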