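"""Closed-loop stimulation controller simulated against virtual patients.

The controller replaces the attending physician: each 1-s window it feeds
the gyroscope RMS features and its own previously *predicted* stimulation
class (free-running, unlike the teacher-forced training phase) to a
trained model, ramps the pulse amplitude toward the predicted class's
maximum (0/5/10/15/20 mA) by at most 1 mA per step, and switches off once
RMS on both x and y axes has dropped 2.5-fold versus the values captured
at stimulation onset. The patient side is the same envelope dynamics used
by the open-loop session simulator, stepped window by window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from tremorkit.dataset import amplitude_to_class, class_to_max_amplitude
from tremorkit.features import rms_windows
from tremorkit.metrics import (
    ReductionCriteria,
    ResetSummary,
    compute_reset_summary,
    stop_criterion_met,
)
from tremorkit.synthetic import (
    SECTION_AFTER,
    SECTION_BEFORE,
    SECTION_DURING,
    TRANSITION_S,
    GyroStream,
    PatientProfile,
    SessionConfig,
)


@dataclass(frozen=True)
class ControllerConfig:
    """Controller cadence and ramp policy.

    One decision per 1-s feature window. ``dwell_steps`` windows must
    elapse at an amplitude level before the next 1 mA increment
    (``dwell_steps=10`` reproduces the manual 10-s dwell; 1 ramps every
    window). ``hold_after_criterion_s`` optionally keeps stimulating for
    that long after the stopping criterion fires (the manual protocol
    held ~30 s); the default stops immediately. Once stopped, the
    controller stays stopped for the session (no re-arm policy).
    """

    ramp_step: float = 1.0
    dwell_steps: int = 10
    hold_after_criterion_s: float = 0.0
    window_s: float = 1.0

    def __post_init__(self) -> None:
        if self.ramp_step <= 0 or self.dwell_steps < 1:
            raise ValueError("ramp_step must be > 0 and dwell_steps >= 1")


@dataclass
class ControllerState:
    phase: str = "idle"  # idle | ramping | holding | stopped
    current_amplitude: float = 0.0
    predicted_class: int = 0
    windows_at_level: int = 0
    stim_start_reference: pd.Series | None = None
    hold_remaining: int = 0


class OracleClassifier:
    """Reference policy: always emits the class containing the patient's
    response threshold (rounded up so the class maximum is effective)."""

    def __init__(self, profile: PatientProfile):
        self.cls = int(amplitude_to_class(float(np.ceil(profile.response_threshold))))

    def stepper(self):
        return self

    def step(self, x) -> int:
        return self.cls


def _as_stepper(model):
    if hasattr(model, "stepper"):
        stepper = model.stepper()
    elif hasattr(model, "step"):
        stepper = model
    else:
        raise ValueError("model must expose .stepper() or .step(); is it trained?")
    if getattr(model, "spec", None) is not None and model.spec.feature_set != "gyro_plus_prev":
        raise ValueError("closed-loop control requires a model trained with gyro_plus_prev features")
    return stepper


def controller_step(
    state: ControllerState,
    window: pd.Series,
    stepper,
    criteria: ReductionCriteria | None = None,
    config: ControllerConfig | None = None,
) -> tuple[ControllerState, float]:
    """One control decision: consume a feature window, command an amplitude.

    The model input is ``(rms_x, rms_y, rms_z, previous predicted
    class)``. The commanded amplitude moves toward the predicted class's
    maximum by at most ``ramp_step`` per call and drops to zero once the
    2.5x stopping rule fires (after the optional hold).
    """
    criteria = criteria or ReductionCriteria()
    config = config or ControllerConfig()
    state = replace(state)

    if state.phase == "stopped":
        state.current_amplitude = 0.0
        return state, 0.0

    x = np.array(
        [window["rms_x"], window["rms_y"], window["rms_z"], state.predicted_class], dtype=float
    )
    state.predicted_class = int(stepper.step(x))

    stimulating = state.current_amplitude > 0
    if stimulating and state.stim_start_reference is not None:
        if state.phase == "holding" and state.hold_remaining > 0:
            state.hold_remaining -= 1
            if state.hold_remaining == 0:
                state.phase = "stopped"
                state.current_amplitude = 0.0
                return state, 0.0
            return state, state.current_amplitude
        if stop_criterion_met(window, state.stim_start_reference, criteria):
            hold_steps = int(round(config.hold_after_criterion_s / config.window_s))
            if hold_steps > 0:
                state.phase = "holding"
                state.hold_remaining = hold_steps
                return state, state.current_amplitude
            state.phase = "stopped"
            state.current_amplitude = 0.0
            return state, 0.0

    target = float(class_to_max_amplitude(state.predicted_class))
    amp = state.current_amplitude
    if amp < target:
        if not stimulating or state.windows_at_level + 1 >= config.dwell_steps:
            amp = min(target, amp + config.ramp_step)
            state.windows_at_level = 0
        else:
            state.windows_at_level += 1
    elif amp > target:
        amp = max(target, amp - config.ramp_step)
        state.windows_at_level = 0
    else:
        state.windows_at_level += 1

    if amp > 0 and not stimulating:
        # stimulation onset: capture the reference RMS for the 2.5x rule
        state.stim_start_reference = window[["rms_x", "rms_y", "rms_z"]].astype(float)
    if amp == 0:
        state.phase = "idle"
    elif amp < target:
        state.phase = "ramping"
    else:
        state.phase = "holding"
    state.current_amplitude = amp
    return state, amp


class _VirtualPatient:
    """Window-by-window tremor generator with the simulator's envelope dynamics."""

    def __init__(self, profile: PatientProfile, sample_rate: float, seed: int):
        self.profile = profile
        self.sr = sample_rate
        self.rng = np.random.default_rng(seed)
        self.phases = self.rng.uniform(0, 2 * np.pi, size=3)
        self.t = 0.0
        self.env = 1.0
        self.off_timer = 0.0
        floor = profile.suppression_floor
        self.down_rate = (1.0 - floor) / TRANSITION_S
        self.up_rate = (
            np.inf if profile.reemergence_ramp == 0 else (1.0 - floor) / profile.reemergence_ramp
        )

    def emit_window(self, amplitude: float, window_s: float = 1.0) -> np.ndarray:
        """Generate one window of (n, 3) samples under the given amplitude."""
        n = int(round(window_s * self.sr))
        dt = 1.0 / self.sr
        p = self.profile
        out = np.empty((n, 3))
        amps = p.baseline_rms * np.sqrt(2.0)
        for k in range(n):
            if amplitude >= p.response_threshold:
                self.env = max(p.suppression_floor, self.env - self.down_rate * dt)
                self.off_timer = 0.0
            elif self.env < 1.0:
                self.off_timer += dt
                if self.off_timer >= p.reset_hold:
                    self.env = min(1.0, self.env + self.up_rate * dt) if np.isfinite(self.up_rate) else 1.0
            for ax in range(3):
                out[k, ax] = self.env * amps[ax] * np.sin(
                    2 * np.pi * p.tremor_freq[ax] * self.t + self.phases[ax]
                )
            self.t += dt
        if p.noise_sd > 0:
            out += self.rng.normal(0.0, p.noise_sd, size=out.shape)
        return out


@dataclass
class ClosedLoopResult:
    summary: ResetSummary
    trace: pd.DataFrame  # per-window commanded amplitude, class, phase
    stream: GyroStream
    windows: pd.DataFrame


def run_closed_loop(
    profile: PatientProfile,
    model,
    session: SessionConfig | None = None,
    controller: ControllerConfig | None = None,
    criteria: ReductionCriteria | None = None,
) -> ClosedLoopResult:
    """Simulate a full session with the controller in the loop.

    Timeline: ``before_duration`` of unstimulated baseline, then the
    controller is active for up to ``max_during_duration`` (it commands
    the amplitude applied to the *next* window), then an unstimulated
    tail of ``after_duration``. The reset summary is computed by the
    session-metrics stage on the resulting stream.
    """
    session = session or SessionConfig()
    controller = controller or ControllerConfig()
    criteria = criteria or ReductionCriteria()
    stepper = _as_stepper(model)
    patient = _VirtualPatient(profile, session.sample_rate, session.seed)

    n_before = int(session.before_duration)
    n_active = int(session.max_during_duration)
    n_after = int(session.after_duration)

    state = ControllerState()
    amplitude = 0.0
    samples = []
    i_t_windows = []
    trace_rows = []

    def _window_features(block: np.ndarray, idx: int) -> pd.Series:
        return pd.Series(
            {
                "window_index": idx,
                "rms_x": float(np.sqrt(np.mean(block[:, 0] ** 2))),
                "rms_y": float(np.sqrt(np.mean(block[:, 1] ** 2))),
                "rms_z": float(np.sqrt(np.mean(block[:, 2] ** 2))),
            }
        )

    idx = 0
    for _ in range(n_before):
        block = patient.emit_window(0.0, controller.window_s)
        samples.append(block)
        i_t_windows.append(0.0)
        idx += 1
    for _ in range(n_active):
        block = patient.emit_window(amplitude, controller.window_s)
        samples.append(block)
        i_t_windows.append(amplitude)
        feats = _window_features(block, idx)
        state, commanded = controller_step(state, feats, stepper, criteria, controller)
        trace_rows.append(
            {
                "window_index": idx,
                "applied_mA": amplitude,
                "commanded_mA": commanded,
                "predicted_class": state.predicted_class,
                "phase": state.phase,
            }
        )
        amplitude = commanded
        idx += 1
        if state.phase == "stopped" and amplitude == 0.0:
            break
    for _ in range(n_after):
        block = patient.emit_window(0.0, controller.window_s)
        samples.append(block)
        i_t_windows.append(0.0)
        idx += 1

    all_samples = np.vstack(samples)
    n = len(all_samples)
    sr = session.sample_rate
    i_t = np.repeat(np.asarray(i_t_windows), int(round(controller.window_s * sr)))
    stim_on = np.nonzero(i_t > 0)[0]
    section = np.full(n, SECTION_BEFORE, dtype=object)
    if stim_on.size:
        section[stim_on[0] : stim_on[-1] + 1] = SECTION_DURING
        section[stim_on[-1] + 1 :] = SECTION_AFTER
        i_t[section != SECTION_DURING] = 0.0
    stream = GyroStream(
        timestamps=np.arange(n) / sr,
        g_x=all_samples[:, 0],
        g_y=all_samples[:, 1],
        g_z=all_samples[:, 2],
        i_t=i_t,
        section=section,
        sample_rate=sr,
        patient_id=profile.patient_id,
    )
    windows = rms_windows(stream, controller.window_s)
    if stim_on.size == 0:
        summary = ResetSummary(
            stim_duration_A=0.0,
            reduction_during_B=0.0,
            continuing_after_C=0.0,
            reset_time_D=0.0,
            max_amplitude=0.0,
            avg_amplitude=0.0,
            never_reduced=True,
        )
    else:
        summary = compute_reset_summary(windows, criteria=criteria, window_s=controller.window_s)
    return ClosedLoopResult(
        summary=summary,
        trace=pd.DataFrame(trace_rows),
        stream=stream,
        windows=windows,
    )


__all__ = [
    "ControllerConfig",
    "ControllerState",
    "OracleClassifier",
    "controller_step",
    "run_closed_loop",
    "ClosedLoopResult",
]
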