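"""Session segmentation and tremor-reduction outcomes, including reset time.

A stimulation session splits into *before* (no stimulation), *during*
(first to last nonzero pulse amplitude) and *after*. Against a baseline
taken from the before section, a window counts as "reduced" when its
3-axis RMS magnitude falls below half of baseline, sustained for a
configurable number of consecutive windows. The tremor reset time ``D``
is the reduced time during stimulation (``B``) plus the reduced time after
withdrawal until the tremor re-emerges toward baseline (``C``):
``D = B + C``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tremorkit.features import rms_magnitude

_EPS = np.finfo(float).eps


@dataclass(frozen=True)
class ReductionCriteria:
    """Thresholds defining tremor reduction and stimulation stopping.

    gyro_reduction_fraction
        Fractional drop in 3-axis RMS magnitude versus baseline that
        counts as tremor reduction (default 0.5: a >50 % reduction).
    stop_ratio
        Stimulation may stop once RMS on both the x and y axes has fallen
        by at least this factor versus the values at stimulation start
        (default 2.5).
    persistence_k
        Consecutive windows required to enter or leave the reduced state.
    reemergence_fraction
        Fraction of baseline magnitude at which the tremor is considered
        re-emerged after withdrawal (default 0.75; the published
        criterion "re-emerged to the pre-stimulation level" fixes no
        threshold).
    """

    gyro_reduction_fraction: float = 0.5
    stop_ratio: float = 2.5
    persistence_k: int = 3
    reemergence_fraction: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.gyro_reduction_fraction < 1.0:
            raise ValueError("gyro_reduction_fraction must be in (0, 1)")
        if self.stop_ratio <= 1.0:
            raise ValueError("stop_ratio must exceed 1")
        if self.persistence_k < 1:
            raise ValueError("persistence_k must be >= 1")
        if not 0.0 < self.reemergence_fraction <= 1.0:
            raise ValueError("reemergence_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SectionBoundaries:
    """Index ranges (positions into the window table) of the 3 sections."""

    before: tuple[int, int]  # half-open [start, stop)
    during: tuple[int, int]
    after: tuple[int, int]
    no_stimulation: bool = False


@dataclass
class ResetSummary:
    """Durations (s) and amplitude statistics of one stimulation bout."""

    stim_duration_A: float
    reduction_during_B: float
    continuing_after_C: float
    reset_time_D: float
    max_amplitude: float
    avg_amplitude: float
    baseline_rms: dict = field(default_factory=dict)
    censored: bool = False
    never_reduced: bool = False

    def __post_init__(self) -> None:
        assert abs(self.reset_time_D - (self.reduction_during_B + self.continuing_after_C)) < 1e-9

    def to_dict(self) -> dict:
        return {
            "stim_duration_A": self.stim_duration_A,
            "reduction_during_B": self.reduction_during_B,
            "continuing_after_C": self.continuing_after_C,
            "reset_time_D": self.reset_time_D,
            "max_amplitude": self.max_amplitude,
            "avg_amplitude": self.avg_amplitude,
            "baseline_rms": self.baseline_rms,
            "censored": self.censored,
            "never_reduced": self.never_reduced,
        }


def segment_session(windows: pd.DataFrame) -> SectionBoundaries:
    """Split windows into before/during/after from the pulse-amplitude trace."""
    i_t = windows["i_t"].to_numpy()
    n = len(i_t)
    on = np.nonzero(i_t > 0)[0]
    if on.size == 0:
        return SectionBoundaries(before=(0, n), during=(n, n), after=(n, n), no_stimulation=True)
    first, last = int(on[0]), int(on[-1]) + 1
    return SectionBoundaries(before=(0, first), during=(first, last), after=(last, n))


def baseline_rms(before_windows: pd.DataFrame, min_windows: int = 30) -> pd.Series:
    """Per-axis median RMS over the before-stimulation section.

    The median is used so that occasional movement-artifact windows do
    not bias the reference.
    """
    if len(before_windows) < min_windows:
        raise ValueError(
            f"need >= {min_windows} before-stimulation windows, got {len(before_windows)}"
        )
    return before_windows[["rms_x", "rms_y", "rms_z"]].median()


def _debounced_states(raw: np.ndarray, k: int) -> np.ndarray:
    """Hysteresis state machine: a state change requires k consecutive
    windows of the opposite condition and is attributed from the start of
    that run."""
    out = np.empty_like(raw, dtype=bool)
    state = False
    i = 0
    n = len(raw)
    while i < n:
        j = i
        while j < n and raw[j] == raw[i]:
            j += 1
        run_val = bool(raw[i])
        if run_val != state and (j - i) >= k:
            state = run_val
        out[i:j] = state
        i = j
    return out


def detect_reduction_state(
    windows: pd.DataFrame,
    baseline: pd.Series,
    criteria: ReductionCriteria | None = None,
) -> np.ndarray:
    """Per-window boolean: tremor reduced versus baseline, with persistence.

    A window's raw condition is ``magnitude < (1 - gyro_reduction_fraction)
    * baseline_magnitude``; the reduced state is entered (and left) only
    after ``persistence_k`` consecutive windows of the new condition, and
    is attributed retroactively from the start of the qualifying run.
    """
    criteria = criteria or ReductionCriteria()
    base_mag = float(np.sqrt(np.sum(np.square(baseline[["rms_x", "rms_y", "rms_z"]].to_numpy()))))
    mag = rms_magnitude(windows)
    raw = mag < (1.0 - criteria.gyro_reduction_fraction) * base_mag
    return _debounced_states(raw, criteria.persistence_k)


def compute_reset_summary(
    windows: pd.DataFrame,
    boundaries: SectionBoundaries | None = None,
    criteria: ReductionCriteria | None = None,
    window_s: float = 1.0,
    baseline: pd.Series | None = None,
) -> ResetSummary:
    """Compute durations A-D and amplitude statistics for one session.

    A: length of the during-stimulation section. B: reduced time within
    it. C: reduced time from stimulation withdrawal until the first
    re-emergence (magnitude at or above ``reemergence_fraction`` of
    baseline for ``persistence_k`` windows); if no re-emergence occurs by
    session end the summary is flagged censored. D = B + C.
    """
    criteria = criteria or ReductionCriteria()
    boundaries = boundaries or segment_session(windows)
    if boundaries.no_stimulation or boundaries.during[0] == boundaries.during[1]:
        raise ValueError("during-stimulation section is empty")
    if baseline is None:
        baseline = baseline_rms(windows.iloc[boundaries.before[0] : boundaries.before[1]])
    reduced = detect_reduction_state(windows, baseline, criteria)

    d0, d1 = boundaries.during
    a0, a1 = boundaries.after
    a = (d1 - d0) * window_s
    b = float(np.sum(reduced[d0:d1])) * window_s

    base_mag = float(np.sqrt(np.sum(np.square(baseline[["rms_x", "rms_y", "rms_z"]].to_numpy()))))
    after = windows.iloc[a0:a1]
    mag_after = rms_magnitude(after) if len(after) else np.array([])
    reemerged = mag_after >= criteria.reemergence_fraction * base_mag
    onset = None
    run = 0
    for idx, val in enumerate(reemerged):
        run = run + 1 if val else 0
        if run >= criteria.persistence_k:
            onset = idx - criteria.persistence_k + 1
            break
    if onset is None:
        censored = len(after) > 0
        c = float(np.sum(reduced[a0:a1])) * window_s
    else:
        censored = False
        c = float(np.sum(reduced[a0 : a0 + onset])) * window_s

    i_during = windows["i_t"].to_numpy()[d0:d1]
    never_reduced = b == 0
    if never_reduced:
        c = 0.0  # no reduction to continue
    return ResetSummary(
        stim_duration_A=a,
        reduction_during_B=b,
        continuing_after_C=c,
        reset_time_D=b + c,
        max_amplitude=float(np.max(i_during)),
        avg_amplitude=float(np.mean(i_during)),
        baseline_rms={k: float(v) for k, v in baseline.items()},
        censored=censored,
        never_reduced=never_reduced,
    )


def stop_criterion_met(
    window: pd.Series,
    reference: pd.Series,
    criteria: ReductionCriteria | None = None,
) -> bool:
    """True once RMS on both x and y has dropped by ``stop_ratio`` versus
    the values captured at stimulation start."""
    criteria = criteria or ReductionCriteria()
    rx = reference["rms_x"] / max(window["rms_x"], _EPS)
    ry = reference["rms_y"] / max(window["rms_y"], _EPS)
    return bool(rx >= criteria.stop_ratio and ry >= criteria.stop_ratio)


__all__ = [
    "ReductionCriteria",
    "SectionBoundaries",
    "ResetSummary",
    "segment_session",
    "baseline_rms",
    "detect_reduction_state",
    "compute_reset_summary",
    "stop_criterion_met",
]
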