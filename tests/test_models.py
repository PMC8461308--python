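"""Model suite: macro metrics, training contracts, grids, patient-wise CV."""

import numpy as np
import pandas as pd
import pytest

from tremorkit.dataset import grouped_folds
from tremorkit.models import (
    DEFAULT_GRIDS,
    FAMILIES,
    ModelSpec,
    confusion_matrix,
    cross_validate,
    grid_search,
    improvement_pct,
    macro_metrics,
    train_predict,
)
from tremorkit.models.lstm import LSTMClassifier
from sklearn.model_selection import ParameterGrid


def brute_force_macro(cm):
    """Independent one-vs-rest recomputation of the printed formulas."""
    cm = np.asarray(cm, dtype=float)
    ps, rs, f1s = [], [], []
    for c in range(cm.shape[0]):
        if cm[c].sum() == 0:
            continue  # class absent from true labels
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c].sum() - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * r * p / (r + p) if r + p else 0.0
        ps.append(p), rs.append(r), f1s.append(f1)
    return np.mean(ps), np.mean(rs), np.mean(f1s), np.trace(cm) / cm.sum()


class TestMacroMetrics:
    def test_perfect_diagonal(self):
        rep = macro_metrics(np.diag([10, 20, 5, 3, 2]))
        assert rep.macro_precision == rep.macro_recall == rep.macro_f1 == 1.0
        assert rep.accuracy == 1.0

    def test_two_class_hand_computation(self):
        cm = np.array([[8, 2], [3, 7]])
        rep = macro_metrics(cm)
        p0, r0 = 8 / 11, 8 / 10
        p1, r1 = 7 / 9, 7 / 10
        f0 = 2 * r0 * p0 / (r0 + p0)
        f1 = 2 * r1 * p1 / (r1 + p1)
        assert rep.macro_f1 == pytest.approx((f0 + f1) / 2)
        assert rep.macro_precision == pytest.approx((p0 + p1) / 2)
        assert rep.accuracy == pytest.approx(15 / 20)

    def test_fully_mispredicted_class_has_zero_accuracy(self):
        cm = np.zeros((5, 5), dtype=int)
        cm[:4, :4] = np.diag([10, 10, 10, 10])
        cm[4, 0] = 6  # class 4 never predicted correctly
        rep = macro_metrics(cm)
        assert rep.per_class_accuracy[4] == 0.0
        assert rep.per_class_f1[4] == 0.0

    def test_absent_classes_excluded_from_macro(self):
        cm = np.zeros((5, 5), dtype=int)
        cm[0, 0] = 10
        cm[1, 1] = 10
        rep = macro_metrics(cm)
        assert list(rep.classes_present) == [0, 1]
        assert rep.macro_f1 == 1.0
        assert np.isnan(rep.per_class_accuracy[4])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            macro_metrics(np.zeros((5, 5)))

    def test_random_matrices_match_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            cm = rng.integers(0, 30, size=(5, 5))
            if cm.sum() == 0:
                continue
            rep = macro_metrics(cm)
            p, r, f1, acc = brute_force_macro(cm)
            assert rep.macro_precision == pytest.approx(p)
            assert rep.macro_recall == pytest.approx(r)
            assert rep.macro_f1 == pytest.approx(f1)
            assert rep.accuracy == pytest.approx(acc)


def test_improvement_formula_on_published_pair():
    # (0.295 -> 0.736): +149.49 % from the rounded table values; the
    # published column prints 149.51 % (computed from unrounded scores)
    assert improvement_pct(0.295, 0.736) == pytest.approx(149.4915, abs=0.01)
    assert improvement_pct(0.295, 0.736) == pytest.approx(149.51, abs=0.15)


def _copy_task_records(n_patients=6, n_windows=120, seed=0):
    """Target equals the previous observed class: any gyro+prev model
    should reach perfect accuracy. The gyroscope features are constant
    (uninformative) so the task is purely the prev-class copy."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        prev = 0
        for w in range(n_windows):
            rows.append(
                {
                    "patient_id": f"P{p}",
                    "window_index": w,
                    "rms_x": 1.0,
                    "rms_y": 2.0,
                    "rms_z": 3.0,
                    "prev_class": prev,
                    "target_class": prev,  # copy of prev
                }
            )
            prev = int(rng.integers(0, 5))  # physician moves to a new level
    return pd.DataFrame(rows)


SMALL_LSTM = {"hidden": 16, "n_layers": 1, "epochs": 200, "lr": 0.003, "batch_size": 4, "chunk_len": 30}


class TestTrainPredict:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_copy_task_is_solved_with_prev_feature(self, family):
        records = _copy_task_records()
        train = records[records.patient_id < "P4"]
        test = records[records.patient_id >= "P4"]
        hp = SMALL_LSTM if family == "lstm" else {}
        spec = ModelSpec(family=family, hyperparameters=hp, feature_set="gyro_plus_prev", seed=0)
        res = train_predict(spec, train, test)
        assert res.report.accuracy >= 0.99

    @pytest.mark.parametrize("family", ["random_forest", "neural_net", "lstm"])
    def test_deterministic_for_fixed_seed(self, family):
        records = _copy_task_records(n_patients=4, n_windows=60)
        train = records[records.patient_id < "P2"]
        test = records[records.patient_id >= "P2"]
        hp = SMALL_LSTM if family == "lstm" else {}
        spec = ModelSpec(family=family, hyperparameters=hp, seed=7)
        r1 = train_predict(spec, train, test)
        r2 = train_predict(spec, train, test)
        assert np.array_equal(r1.predictions.to_numpy(), r2.predictions.to_numpy())

    def test_patient_overlap_rejected(self):
        records = _copy_task_records(n_patients=3, n_windows=20)
        with pytest.raises(ValueError, match="share patients"):
            train_predict(ModelSpec("logistic_regression"), records, records)

    def test_single_class_training_flagged_degenerate(self):
        records = _copy_task_records(n_patients=4, n_windows=20)
        train = records[records.patient_id < "P2"].copy()
        train["target_class"] = 2
        test = records[records.patient_id >= "P2"]
        res = train_predict(ModelSpec("logistic_regression"), train, test)
        assert res.degenerate
        assert (res.predictions == 2).all()

    def test_gyro_only_on_independent_targets_is_chance_level(self):
        rng = np.random.default_rng(4)
        n = 1200
        records = pd.DataFrame(
            {
                "patient_id": np.repeat([f"P{i}" for i in range(6)], n // 6),
                "window_index": np.tile(np.arange(n // 6), 6),
                "rms_x": rng.normal(size=n),
                "rms_y": rng.normal(size=n),
                "rms_z": rng.normal(size=n),
                "prev_class": 0,
                "target_class": rng.choice([0, 1], size=n, p=[0.7, 0.3]),
            }
        )
        train = records[records.patient_id < "P4"]
        test = records[records.patient_id >= "P4"]
        res = train_predict(ModelSpec("logistic_regression", feature_set="gyro_only"), train, test)
        majority = (test.target_class == 0).mean()
        assert res.report.accuracy == pytest.approx(majority, abs=0.1)

    def test_normalization_contract_enforced(self):
        with pytest.raises(ValueError, match="normalization"):
            ModelSpec("svm", normalization=False)
        with pytest.raises(ValueError, match="normalization"):
            ModelSpec("random_forest", normalization=True)


class TestGridSearch:
    def test_published_rf_grid_cardinality(self):
        assert len(list(ParameterGrid(DEFAULT_GRIDS["random_forest"]))) == 6 * 2 * 2 * 5
        assert len(list(ParameterGrid(DEFAULT_GRIDS["svm"]))) == 3 * 4
        assert len(list(ParameterGrid(DEFAULT_GRIDS["neural_net"]))) == 6 * 2 * 3

    def test_singleton_grid_returned(self):
        records = _copy_task_records(n_patients=4, n_windows=40)
        res = grid_search(
            "svm", records, grid={"C": [1.0], "kernel": ["rbf"]}, inner_k=2, seed=0
        )
        assert res.best_params == {"C": 1.0, "kernel": "rbf"}
        assert len(res.table) == 1

    def test_planted_optimum_kernel_selected(self):
        """Concentric classes: only the RBF kernel separates them."""
        rng = np.random.default_rng(8)
        rows = []
        for p in range(6):
            for w in range(150):
                cls = int(rng.integers(0, 2))
                radius = 1.0 if cls == 0 else 3.0
                angle = rng.uniform(0, 2 * np.pi)
                rows.append(
                    {
                        "patient_id": f"P{p}",
                        "window_index": w,
                        "rms_x": radius * np.cos(angle) + rng.normal(0, 0.1),
                        "rms_y": radius * np.sin(angle) + rng.normal(0, 0.1),
                        "rms_z": rng.normal(),
                        "prev_class": 0,
                        "target_class": cls,
                    }
                )
        records = pd.DataFrame(rows)
        res = grid_search(
            "svm",
            records,
            grid={"C": [1.0], "kernel": ["linear", "rbf"]},
            feature_set="gyro_only",
            inner_k=2,
            seed=0,
        )
        assert res.best_params["kernel"] == "rbf"

    def test_empty_grid_and_unknown_family_rejected(self):
        records = _copy_task_records(n_patients=4, n_windows=10)
        with pytest.raises(ValueError, match="empty"):
            grid_search("svm", records, grid={})
        with pytest.raises(ValueError, match="no grid"):
            grid_search("logistic_regression", records)


class TestCrossValidate:
    def test_perfect_copy_task(self):
        records = _copy_task_records(n_patients=6, n_windows=80)
        folds = grouped_folds(records.patient_id, k=3, seed=0)
        rep = cross_validate(ModelSpec("logistic_regression"), records, folds)
        assert rep.mean_accuracy == 1.0
        assert rep.sd_accuracy == 0.0
        assert len(rep.per_fold) == 3

    def test_uncovered_records_rejected(self):
        records = _copy_task_records(n_patients=4, n_windows=10)
        folds = grouped_folds(["Q1", "Q2", "Q3"], k=3, seed=0)
        with pytest.raises(ValueError):
            cross_validate(ModelSpec("logistic_regression"), records, folds)


class TestLSTMInternals:
    def test_analytic_gradients_match_numerical(self):
        m = LSTMClassifier(n_features=3, n_classes=4, hidden=5, n_layers=2, chunk_len=7, seed=0)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2, 7, 3))
        y = rng.integers(0, 4, size=(2, 7))
        mask = np.ones((2, 7), dtype=bool)
        mask[1, 5:] = False
        _, grads = m.loss_and_grads(X, y, mask)
        eps = 1e-6
        params = m._params()
        for pi, p in enumerate(params):
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                l1, _ = m.loss_and_grads(X, y, mask)
                p[idx] = orig - eps
                l2, _ = m.loss_and_grads(X, y, mask)
                p[idx] = orig
                num = (l1 - l2) / (2 * eps)
                assert grads[pi][idx] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_learns_per_step_labels(self):
        rng = np.random.default_rng(1)
        seqs = []
        for _ in range(10):
            y = rng.integers(0, 3, size=60)
            X = np.stack([y.astype(float), rng.normal(size=60)], axis=1)
            seqs.append((X, y))
        m = LSTMClassifier(
            n_features=2, n_classes=3, hidden=16, n_layers=1, epochs=100, lr=0.01, chunk_len=20, seed=0
        )
        m.fit(seqs)
        acc = np.mean([np.mean(m.predict_sequence(X) == y) for X, y in seqs])
        assert acc > 0.97
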