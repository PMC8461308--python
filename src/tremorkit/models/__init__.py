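"""Stimulation-class predictors, grids, patient-wise CV, macro metrics.

Five model families predict the 5-level stimulation class from 1-s
gyroscope RMS features, optionally augmented with the previous observed
stimulation level (teacher forcing): logistic regression, random forest,
SVM (RBF), a feed-forward neural network, and an LSTM. The scikit-learn
families treat each 1-s record independently; the LSTM consumes
per-patient chronological sequences. Features are standardized (training
folds only) for SVM, NN and LSTM; evaluation uses macro-averaged
one-vs-rest precision/recall/F1 and accuracy over patient-wise folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from tremorkit.dataset import FoldAssignment, grouped_folds
from tremorkit.models.lstm import LSTMClassifier

FAMILIES = ("logistic_regression", "random_forest", "svm", "neural_net", "lstm")
#: Families whose inputs are standardized (fit on training data only).
NORMALIZED_FAMILIES = frozenset({"svm", "neural_net", "lstm"})

FEATURE_SETS = {
    "gyro_only": ["rms_x", "rms_y", "rms_z"],
    "gyro_plus_prev": ["rms_x", "rms_y", "rms_z", "prev_class"],
}

N_CLASSES = 5

#: Published hyperparameter grids for the exhaustive search.
DEFAULT_GRIDS = {
    "random_forest": {
        "n_estimators": [50, 100, 200, 300, 400, 500],
        "bootstrap": [True, False],
        "criterion": ["gini", "entropy"],
        "min_samples_leaf": [2, 5, 10, 20, 30],
    },
    "svm": {
        "C": [0.5, 1, 2],
        "kernel": ["linear", "poly", "rbf", "sigmoid"],
    },
    "neural_net": {
        "hidden_layer_sizes": [(50,), (100,), (200,), (50, 50), (100, 100), (200, 200)],
        "activation": ["tanh", "relu"],
        "solver": ["lbfgs", "sgd", "adam"],
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one predictor.

    ``normalization`` defaults to the family convention (on for SVM, NN
    and LSTM; off for logistic regression and random forest) and an
    explicit value that contradicts it raises ``ValueError``.
    """

    family: str
    hyperparameters: dict = field(default_factory=dict)
    feature_set: str = "gyro_plus_prev"
    normalization: bool | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature_set {self.feature_set!r}")
        expected = self.family in NORMALIZED_FAMILIES
        if self.normalization is None:
            object.__setattr__(self, "normalization", expected)
        elif self.normalization != expected:
            raise ValueError(
                f"normalization must be {'on' if expected else 'off'} for {self.family}"
            )

    @property
    def features(self) -> list[str]:
        return FEATURE_SETS[self.feature_set]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_matrix(y_true, y_pred, n_classes: int = N_CLASSES) -> np.ndarray:
    """Counts matrix: rows = true class, columns = predicted class."""
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (np.asarray(y_true, dtype=int), np.asarray(y_pred, dtype=int)), 1)
    return cm


@dataclass
class EvalReport:
    """Macro-averaged one-vs-rest metrics from a confusion matrix."""

    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    per_class_accuracy: np.ndarray
    classes_present: np.ndarray
    n: int

    def to_dict(self) -> dict:
        return {
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "per_class_precision": self.per_class_precision.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "per_class_f1": self.per_class_f1.tolist(),
            "per_class_accuracy": [
                None if np.isnan(v) else v for v in self.per_class_accuracy
            ],
            "classes_present": self.classes_present.tolist(),
            "n": self.n,
        }


def macro_metrics(cm: np.ndarray) -> EvalReport:
    """Per-class precision P = tp/(tp+fp), recall R = tp/(tp+fn) and
    F1 = 2RP/(R+P), with 0/0 defined as 0; macro values are the unweighted
    mean over classes present in the true labels. Accuracy is the trace
    over the total; per-class accuracy the diagonal over the row sum
    (NaN for absent classes).
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0, 2 * recall * precision / (recall + precision), 0.0)
        row = cm.sum(axis=1).astype(float)
        per_class_acc = np.where(row > 0, tp / np.where(row > 0, row, 1.0), np.nan)
    present = cm.sum(axis=1) > 0
    return EvalReport(
        macro_precision=float(precision[present].mean()),
        macro_recall=float(recall[present].mean()),
        macro_f1=float(f1[present].mean()),
        accuracy=float(tp.sum() / total),
        per_class_precision=precision,
        per_class_recall=recall,
        per_class_f1=f1,
        per_class_accuracy=per_class_acc,
        classes_present=np.nonzero(present)[0],
        n=int(total),
    )


def improvement_pct(baseline: float, improved: float) -> float:
    """Relative improvement (%) of a metric over its feature-ablated baseline."""
    return (improved - baseline) / baseline * 100.0


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _build_sklearn(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.family == "logistic_regression":
        # baseline model: library defaults, no grid search
        return LogisticRegression(max_iter=1000, random_state=spec.seed, **hp)
    if spec.family == "random_forest":
        hp.setdefault("n_estimators", 100)
        hp.setdefault("bootstrap", True)
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.family == "svm":
        hp.setdefault("C", 1.0)
        hp.setdefault("kernel", "rbf")
        return SVC(random_state=spec.seed, **hp)
    if spec.family == "neural_net":
        hp.setdefault("hidden_layer_sizes", (100, 100))
        hp.setdefault("max_iter", 500)
        return MLPClassifier(random_state=spec.seed, **hp)
    raise ValueError(spec.family)


@dataclass
class FittedModel:
    """A trained predictor with its (optional) input scaler."""

    spec: ModelSpec
    estimator: object
    scaler: StandardScaler | None
    degenerate_class: int | None = None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return self.scaler.transform(X) if self.scaler is not None else X

    def predict_rows(self, X: np.ndarray) -> np.ndarray:
        """Row-wise predictions (records treated independently)."""
        X = self._transform(np.asarray(X, dtype=float))
        if self.degenerate_class is not None:
            return np.full(len(X), self.degenerate_class, dtype=int)
        if self.spec.family == "lstm":
            # no recurrent context: run each row as a length-1 sequence
            return np.array([self.estimator.predict_sequence(x[None, :])[0] for x in X])
        return self.estimator.predict(X).astype(int)

    def predict_sequence(self, X: np.ndarray) -> np.ndarray:
        """Predictions for one chronological sequence (recurrent state kept)."""
        X = self._transform(np.asarray(X, dtype=float))
        if self.degenerate_class is not None:
            return np.full(len(X), self.degenerate_class, dtype=int)
        if self.spec.family == "lstm":
            return self.estimator.predict_sequence(X)
        return self.estimator.predict(X).astype(int)

    def stepper(self):
        """One-window-at-a-time interface for closed-loop control."""
        if self.degenerate_class is not None:
            cls = self.degenerate_class
            return _ConstantStepper(cls)
        if self.spec.family == "lstm":
            return _ScaledLSTMStepper(self)
        return _RowStepper(self)


class _ConstantStepper:
    def __init__(self, cls: int):
        self.cls = int(cls)

    def step(self, x) -> int:
        return self.cls


class _RowStepper:
    def __init__(self, fitted: FittedModel):
        self.fitted = fitted

    def step(self, x) -> int:
        return int(self.fitted.predict_rows(np.asarray(x, dtype=float)[None, :])[0])


class _ScaledLSTMStepper:
    def __init__(self, fitted: FittedModel):
        self.fitted = fitted
        self.inner = fitted.estimator.begin_sequence()

    def step(self, x) -> int:
        x = np.asarray(x, dtype=float)[None, :]
        return self.inner.step(self.fitted._transform(x)[0])


def _sequences(records: pd.DataFrame, features: list[str], scaler: StandardScaler | None):
    seqs = []
    index_order = []
    for _, grp in records.groupby("patient_id", sort=True):
        grp = grp.sort_values("window_index")
        X = grp[features].to_numpy(dtype=float)
        if scaler is not None:
            X = scaler.transform(X)
        seqs.append((X, grp["target_class"].to_numpy(dtype=int)))
        index_order.append(grp.index.to_numpy())
    return seqs, index_order


@dataclass
class TrainPredictResult:
    fitted: FittedModel
    predictions: pd.Series  # indexed like the test records
    cm: np.ndarray
    report: EvalReport
    degenerate: bool = False


def train_predict(
    spec: ModelSpec,
    train_records: pd.DataFrame,
    test_records: pd.DataFrame,
) -> TrainPredictResult:
    """Fit on training records and predict the held-out test records.

    Train and test must be patient-disjoint. Normalization parameters are
    fitted on training data only. The LSTM trains and is evaluated on
    per-patient chronological sequences with the observed previous class
    as an input feature (teacher forcing in both phases, matching the
    collection protocol); the other families treat records independently.
    Single-class training data yields a flagged constant predictor.
    """
    overlap = set(train_records["patient_id"]) & set(test_records["patient_id"])
    if overlap:
        raise ValueError(f"train/test share patients: {sorted(overlap)[:5]}")
    features = spec.features
    X_train = train_records[features].to_numpy(dtype=float)
    y_train = train_records["target_class"].to_numpy(dtype=int)
    scaler = None
    if spec.normalization:
        scaler = StandardScaler().fit(X_train)

    classes = np.unique(y_train)
    if classes.size < 2:
        fitted = FittedModel(spec, None, scaler, degenerate_class=int(classes[0]))
        preds = fitted.predict_rows(test_records[features].to_numpy(dtype=float))
        pred_series = pd.Series(preds, index=test_records.index)
        cm = confusion_matrix(test_records["target_class"], preds)
        return TrainPredictResult(fitted, pred_series, cm, macro_metrics(cm), degenerate=True)

    if spec.family == "lstm":
        hp = dict(spec.hyperparameters)
        model = LSTMClassifier(n_features=len(features), n_classes=N_CLASSES, seed=spec.seed, **hp)
        train_seqs, _ = _sequences(train_records, features, scaler)
        model.fit(train_seqs)
        fitted = FittedModel(spec, model, scaler)
        test_seqs, index_order = _sequences(test_records, features, scaler)
        pred_series = pd.Series(0, index=test_records.index, dtype=int)
        for (X, _), idx in zip(test_seqs, index_order):
            pred_series.loc[idx] = model.predict_sequence(X)
    else:
        est = _build_sklearn(spec)
        Xt = scaler.transform(X_train) if scaler is not None else X_train
        est.fit(Xt, y_train)
        fitted = FittedModel(spec, est, scaler)
        preds = fitted.predict_rows(test_records[features].to_numpy(dtype=float))
        pred_series = pd.Series(preds, index=test_records.index)

    cm = confusion_matrix(test_records["target_class"], pred_series.to_numpy())
    return TrainPredictResult(fitted, pred_series, cm, macro_metrics(cm))


# ---------------------------------------------------------------------------
# Grid search and cross-validation
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    best_params: dict
    table: pd.DataFrame  # one row per candidate with mean inner macro-F1


def grid_search(
    family: str,
    train_records: pd.DataFrame,
    grid: dict | None = None,
    feature_set: str = "gyro_plus_prev",
    inner_k: int = 2,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive search over the hyperparameter grid, selected by mean
    macro-F1 on an inner patient-wise split of the training folds.

    Only the three grid-searched families are supported (logistic
    regression is the no-grid baseline; the LSTM is configured manually).
    """
    if family not in DEFAULT_GRIDS:
        raise ValueError(f"no grid defined for family {family!r}")
    grid = grid if grid is not None else DEFAULT_GRIDS[family]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    candidates = list(ParameterGrid(grid))
    if not candidates:
        raise ValueError("empty hyperparameter grid")
    inner = grouped_folds(train_records["patient_id"], k=inner_k, seed=seed)
    fold_ids = inner.fold_of(train_records)
    rows = []
    best = (-np.inf, None)
    for params in candidates:
        spec = ModelSpec(family=family, hyperparameters=params, feature_set=feature_set, seed=seed)
        scores = []
        for fold in range(inner_k):
            tr = train_records.loc[fold_ids != fold]
            te = train_records.loc[fold_ids == fold]
            if len(te) == 0 or len(tr) == 0:
                continue
            scores.append(train_predict(spec, tr, te).report.macro_f1)
        mean_f1 = float(np.mean(scores)) if scores else -np.inf
        rows.append({**params, "mean_macro_f1": mean_f1})
        if mean_f1 > best[0]:
            best = (mean_f1, params)
    return GridSearchResult(best_params=best[1], table=pd.DataFrame(rows))


@dataclass
class CVReport:
    """Per-fold and aggregate performance of one model/feature-set pair."""

    spec: ModelSpec
    per_fold: pd.DataFrame
    mean_macro_f1: float
    sd_macro_f1: float
    mean_accuracy: float
    sd_accuracy: float
    pooled_cm: np.ndarray
    pooled: EvalReport
    absent_classes: dict

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "feature_set": self.spec.feature_set,
            "seed": self.spec.seed,
            "hyperparameters": {k: str(v) for k, v in self.spec.hyperparameters.items()},
            "per_fold": self.per_fold.to_dict(orient="records"),
            "mean_macro_f1": self.mean_macro_f1,
            "sd_macro_f1": self.sd_macro_f1,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "pooled": self.pooled.to_dict(),
            "absent_classes": {str(k): v for k, v in self.absent_classes.items()},
        }


def cross_validate(
    spec: ModelSpec,
    records: pd.DataFrame,
    folds: FoldAssignment,
) -> CVReport:
    """Patient-wise k-fold cross-validation: train on k-1 folds, test on
    the held-out fold; report per-fold and mean +/- SD macro-F1 and
    accuracy. Classes absent from a fold's test labels are excluded from
    that fold's macro average and logged."""
    fold_ids = folds.fold_of(records)
    if np.any(pd.isna(fold_ids)):
        raise ValueError("fold assignment does not cover all records")
    rows = []
    cms = []
    absent = {}
    for fold in range(folds.k):
        test = records.loc[fold_ids == fold]
        train = records.loc[fold_ids != fold]
        if len(test) == 0:
            raise ValueError(f"fold {fold} has no test records")
        res = train_predict(spec, train, test)
        cms.append(res.cm)
        absent[fold] = sorted(set(range(N_CLASSES)) - set(res.report.classes_present.tolist()))
        rows.append(
            {
                "fold": fold,
                "n": res.report.n,
                "macro_precision": res.report.macro_precision,
                "macro_recall": res.report.macro_recall,
                "macro_f1": res.report.macro_f1,
                "accuracy": res.report.accuracy,
                "degenerate": res.degenerate,
            }
        )
    per_fold = pd.DataFrame(rows)
    pooled_cm = np.sum(cms, axis=0)
    return CVReport(
        spec=spec,
        per_fold=per_fold,
        mean_macro_f1=float(per_fold["macro_f1"].mean()),
        sd_macro_f1=float(per_fold["macro_f1"].std(ddof=1)) if folds.k > 1 else 0.0,
        mean_accuracy=float(per_fold["accuracy"].mean()),
        sd_accuracy=float(per_fold["accuracy"].std(ddof=1)) if folds.k > 1 else 0.0,
        pooled_cm=pooled_cm,
        pooled=macro_metrics(pooled_cm),
        absent_classes=absent,
    )


def compare_feature_sets(
    family: str,
    records: pd.DataFrame,
    folds: FoldAssignment,
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> dict:
    """Cross-validate a family with and without the previous-level feature
    and report the relative improvement (%) on macro-F1 and accuracy."""
    reports = {}
    for fs in ("gyro_only", "gyro_plus_prev"):
        spec = ModelSpec(family=family, hyperparameters=hyperparameters or {}, feature_set=fs, seed=seed)
        reports[fs] = cross_validate(spec, records, folds)
    base, full = reports["gyro_only"], reports["gyro_plus_prev"]
    return {
        "family": family,
        "gyro_only": base,
        "gyro_plus_prev": full,
        "improvement_macro_f1_pct": improvement_pct(base.mean_macro_f1, full.mean_macro_f1),
        "improvement_accuracy_pct": improvement_pct(base.mean_accuracy, full.mean_accuracy),
    }


__all__ = [
    "FAMILIES",
    "FEATURE_SETS",
    "DEFAULT_GRIDS",
    "N_CLASSES",
    "ModelSpec",
    "EvalReport",
    "confusion_matrix",
    "macro_metrics",
    "improvement_pct",
    "FittedModel",
    "TrainPredictResult",
    "train_predict",
    "GridSearchResult",
    "grid_search",
    "CVReport",
    "cross_validate",
    "compare_feature_sets",
    "LSTMClassifier",
]
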