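"""Labelled multiclass dataset construction and patient-wise folds.

The pulse amplitude (mA) is discretized into five stimulation classes:

====================  =====
amplitude (mA)        class
====================  =====
0                     0
1-5                   1
6-10                  2
11-15                 3
>= 16                 4
====================  =====

Each 1-s feature window becomes one record with the per-axis RMS, the
previous window's *observed* class (teacher forcing) and the target class.
Records are filtered for manual-adjustment artifacts, and the cohort is
split into patient-wise folds so no patient contributes to both training
and test sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tremorkit.metrics import ReductionCriteria, baseline_rms, detect_reduction_state, segment_session

RECORD_COLUMNS = [
    "patient_id",
    "window_index",
    "rms_x",
    "rms_y",
    "rms_z",
    "prev_class",
    "target_class",
]

_CLASS_MAX_AMPLITUDE = {0: 0.0, 1: 5.0, 2: 10.0, 3: 15.0, 4: 20.0}


def amplitude_to_class(amplitude):
    """Map pulse amplitude (mA) to stimulation class 0-4.

    Non-integer amplitudes are floored to the nearest lower integer
    before the table lookup (the protocol only uses integer steps; the
    floor guards real logs). Negative amplitudes raise ``ValueError``.
    """
    amp = np.asarray(amplitude, dtype=float)
    if np.any(amp < 0):
        raise ValueError("pulse amplitude must be >= 0")
    mA = np.floor(amp)
    cls = np.select(
        [mA == 0, mA <= 5, mA <= 10, mA <= 15],
        [0, 1, 2, 3],
        default=4,
    )
    if np.isscalar(amplitude) or np.ndim(amplitude) == 0:
        return int(cls)
    return cls.astype(int)


def class_to_max_amplitude(cls):
    """Maximum pulse amplitude (mA) for a stimulation class: 0, 5, 10, 15, 20."""
    arr = np.asarray(cls, dtype=float)
    if np.any(arr != np.floor(arr)) or np.any((arr < 0) | (arr > 4)):
        raise ValueError("stimulation class must be an integer in 0..4")
    if np.isscalar(cls) or np.ndim(cls) == 0:
        return _CLASS_MAX_AMPLITUDE[int(arr)]
    return np.array([_CLASS_MAX_AMPLITUDE[int(c)] for c in arr.ravel()]).reshape(arr.shape)


def build_records(windows: pd.DataFrame, patient_id: str | None = None) -> pd.DataFrame:
    """Turn one patient's feature windows into labelled records.

    ``target_class`` discretizes the window's own amplitude;
    ``prev_class`` is the observed class of the previous window (teacher
    forcing), padded with class 0 at the start of the sequence.
    """
    if patient_id is None:
        patient_id = str(windows["patient_id"].iloc[0]) if "patient_id" in windows else "anon"
    windows = windows.sort_values("window_index")
    target = amplitude_to_class(windows["i_t"].to_numpy())
    target = np.atleast_1d(target)
    prev = np.concatenate([[0], target[:-1]])
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "window_index": windows["window_index"].to_numpy(),
            "rms_x": windows["rms_x"].to_numpy(),
            "rms_y": windows["rms_y"].to_numpy(),
            "rms_z": windows["rms_z"].to_numpy(),
            "prev_class": prev,
            "target_class": target,
        }
    )


def filter_records(
    records: pd.DataFrame,
    windows: pd.DataFrame,
    criteria: ReductionCriteria | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop manual-adjustment artifacts from one patient's records.

    Removes during-stimulation windows in which the tremor is present
    (not in the reduced state) yet the applied amplitude is zero — the
    footprint of the physician switching stimulation off mid-exploration.
    Returns the retained records and a removal log (window index and
    reason).
    """
    criteria = criteria or ReductionCriteria()
    boundaries = segment_session(windows)
    removal_log = pd.DataFrame(columns=["window_index", "reason"])
    if boundaries.no_stimulation:
        return records.copy(), removal_log
    base = baseline_rms(windows.iloc[boundaries.before[0] : boundaries.before[1]])
    reduced = detect_reduction_state(windows, base, criteria)
    d0, d1 = boundaries.during
    in_during = np.zeros(len(windows), dtype=bool)
    in_during[d0:d1] = True
    bad = in_during & ~reduced & (windows["i_t"].to_numpy() == 0)
    bad_idx = windows["window_index"].to_numpy()[bad]
    removal_log = pd.DataFrame(
        {
            "window_index": bad_idx,
            "reason": "no amplitude assigned during tremor (manual adjustment)",
        }
    )
    keep = ~records["window_index"].isin(bad_idx)
    return records.loc[keep].reset_index(drop=True), removal_log


@dataclass(frozen=True)
class FoldAssignment:
    """Patient-wise fold assignment for grouped cross-validation."""

    k: int
    patient_to_fold: dict

    def patients_in_fold(self, fold: int) -> list:
        return [p for p, f in self.patient_to_fold.items() if f == fold]

    def fold_of(self, records: pd.DataFrame) -> np.ndarray:
        return records["patient_id"].map(self.patient_to_fold).to_numpy()


def grouped_folds(patients, k: int = 3, seed: int = 0) -> FoldAssignment:
    """Shuffle patients by seed and split as evenly as possible into ``k``
    folds; larger folds come first (20 patients, k=3 gives 7/7/6)."""
    patients = list(dict.fromkeys(patients))  # stable unique
    if k > len(patients):
        raise ValueError(f"k={k} exceeds the number of patients ({len(patients)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    sizes = [len(patients) // k + (1 if i < len(patients) % k else 0) for i in range(k)]
    mapping = {}
    pos = 0
    for fold, size in enumerate(sizes):
        for idx in order[pos : pos + size]:
            mapping[patients[idx]] = fold
        pos += size
    return FoldAssignment(k=k, patient_to_fold=mapping)


def fold_summary(records: pd.DataFrame, assignment: FoldAssignment) -> pd.DataFrame:
    """Per-fold class counts and percentages, plus a totals row.

    Percentages are recomputed from counts (count / fold total x 100); an
    empty class yields 0 without a division error.
    """
    folds = assignment.fold_of(records)
    if np.any(pd.isna(folds)):
        raise ValueError("assignment does not cover every record's patient")
    rows = []
    classes = list(range(5))
    for fold in range(assignment.k):
        sub = records.loc[folds == fold, "target_class"]
        counts = sub.value_counts().reindex(classes, fill_value=0)
        total = int(counts.sum())
        row = {"fold": fold, "n_patients": len(assignment.patients_in_fold(fold))}
        for c in classes:
            row[f"count_{c}"] = int(counts[c])
            row[f"pct_{c}"] = 100.0 * counts[c] / total if total else 0.0
        row["total"] = total
        rows.append(row)
    out = pd.DataFrame(rows)
    total_row = {"fold": "total", "n_patients": int(out["n_patients"].sum())}
    grand = int(out["total"].sum())
    for c in classes:
        csum = int(out[f"count_{c}"].sum())
        total_row[f"count_{c}"] = csum
        total_row[f"pct_{c}"] = 100.0 * csum / grand if grand else 0.0
    total_row["total"] = grand
    return pd.concat([out, pd.DataFrame([total_row])], ignore_index=True)


__all__ = [
    "RECORD_COLUMNS",
    "amplitude_to_class",
    "class_to_max_amplitude",
    "build_records",
    "filter_records",
    "FoldAssignment",
    "grouped_folds",
    "fold_summary",
]
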