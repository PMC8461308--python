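"""Virtual parkinsonian tremor patients and simulated EMS sessions.

The clinical recordings behind this analysis pipeline (wrist-gyroscope logs
of resting tremor under electrical muscle stimulation) are not publicly
available, so this module provides a generative stand-in with the
statistical structure the downstream analysis assumes:

* a ~4-6 Hz resting-tremor oscillation on three gyroscope axes with
  patient-specific amplitude (heavily right-skewed across patients, as in
  published cohort summaries of RMS angular velocity);
* suppression of the oscillation once the stimulation pulse amplitude
  reaches a patient-specific response threshold, down to a residual
  fraction (``suppression_floor``) of the baseline amplitude;
* sustained suppression after stimulation withdrawal (``reset_hold``)
  followed by a linear re-emergence to baseline (``reemergence_ramp``);
* the stepped manual protocol: pulse amplitude raised by 1 mA roughly
  every 10 s until the response threshold is reached, then held ~30 s.

Sessions are emitted as :class:`GyroStream` objects and round-trip through
a plain CSV format mirroring the glove's cloud logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SECTION_BEFORE = "before"
SECTION_DURING = "during"
SECTION_AFTER = "after"

#: Smoothing interval (s) over which the tremor envelope slews between
#: baseline and the suppressed level; avoids discontinuities without
#: materially affecting 1-s aggregates.
TRANSITION_S = 0.5


class ConfigurationError(ValueError):
    """Invalid generator or session configuration."""


class GloveCsvError(ValueError):
    """Malformed glove CSV log."""


@dataclass(frozen=True)
class PatientProfile:
    """Generative parameters for one virtual patient.

    Parameters
    ----------
    tremor_freq : array-like of 3 floats
        Dominant tremor frequency per gyroscope axis, Hz. Must lie in
        (2, 12) Hz, the plausible band for parkinsonian resting tremor.
    baseline_rms : array-like of 3 floats
        RMS angular velocity per axis at rest (gyro units). The tremor
        sinusoid amplitude per axis is ``baseline_rms * sqrt(2)``.
    response_threshold : float
        Pulse amplitude (mA) at and above which stimulation suppresses
        the tremor.
    suppression_floor : float
        Fraction of baseline amplitude remaining under effective
        stimulation; must be in (0, 0.5) so effective stimulation always
        satisfies the >50 % reduction criterion.
    reset_hold : float
        Seconds of continued full suppression after stimulation
        withdrawal.
    reemergence_ramp : float
        Seconds over which the amplitude returns linearly to baseline
        after the hold.
    noise_sd : float
        Standard deviation of additive Gaussian sensor noise (gyro units).
    """

    patient_id: str
    tremor_freq: np.ndarray
    baseline_rms: np.ndarray
    response_threshold: float
    suppression_floor: float
    reset_hold: float
    reemergence_ramp: float
    noise_sd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "tremor_freq", np.asarray(self.tremor_freq, dtype=float))
        object.__setattr__(self, "baseline_rms", np.asarray(self.baseline_rms, dtype=float))
        if self.tremor_freq.shape != (3,) or self.baseline_rms.shape != (3,):
            raise ConfigurationError("tremor_freq and baseline_rms must have 3 axes")
        if not np.all((self.tremor_freq > 2.0) & (self.tremor_freq < 12.0)):
            raise ConfigurationError("tremor_freq must lie within (2, 12) Hz")
        if np.any(self.baseline_rms <= 0):
            raise ConfigurationError("baseline_rms must be positive")
        if not 0.0 < self.suppression_floor < 0.5:
            raise ConfigurationError("suppression_floor must be in (0, 0.5)")
        if self.response_threshold <= 0:
            raise ConfigurationError("response_threshold must be positive")
        if self.reset_hold < 0 or self.reemergence_ramp < 0:
            raise ConfigurationError("reset_hold and reemergence_ramp must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortSettings:
    """Distributions from which :func:`generate_patient` draws profiles.

    Defaults target the scale of published cohort summaries for
    tremor-dominant Parkinson's disease: per-axis dominant frequency
    ~5.5 Hz (SD ~1.7) truncated to (2.5, 11) Hz; per-axis baseline RMS
    log-normal with means ~(13.2, 16.0, 8.3) and SDs roughly 1.5-2x the
    mean (strong right skew); response thresholds spanning 3-17 mA
    (mean ~9.5); suppression floors uniform on (0.1, 0.4); post-stimulation
    hold log-normal around ~2 min; linear re-emergence over 10-40 s.
    """

    freq_mean: float = 5.5
    freq_sd: float = 1.7
    freq_bounds: tuple[float, float] = (2.5, 11.0)
    rms_mean: tuple[float, float, float] = (13.19, 16.04, 8.25)
    rms_sd: tuple[float, float, float] = (19.46, 30.45, 12.80)
    rms_bounds: tuple[float, float] = (0.1, 130.0)
    threshold_mean: float = 9.45
    threshold_sd: float = 4.29
    threshold_bounds: tuple[float, float] = (3.0, 17.0)
    floor_bounds: tuple[float, float] = (0.1, 0.4)
    hold_median: float = 100.0
    hold_log_sd: float = 0.8
    hold_bounds: tuple[float, float] = (0.0, 600.0)
    ramp_bounds: tuple[float, float] = (10.0, 40.0)
    noise_frac_bounds: tuple[float, float] = (0.05, 0.15)

    def __post_init__(self) -> None:
        for lo, hi in (
            self.freq_bounds,
            self.rms_bounds,
            self.threshold_bounds,
            self.floor_bounds,
            self.hold_bounds,
            self.ramp_bounds,
            self.noise_frac_bounds,
        ):
            if not lo <= hi:
                raise ConfigurationError("distribution bounds must satisfy lo <= hi")
        if self.freq_bounds[0] <= 2.0 or self.freq_bounds[1] >= 12.0:
            raise ConfigurationError("freq_bounds must lie strictly inside (2, 12) Hz")
        if not (0.0 < self.floor_bounds[0] and self.floor_bounds[1] < 0.5):
            raise ConfigurationError("floor_bounds must lie inside (0, 0.5)")


@dataclass(frozen=True)
class SessionConfig:
    """Timing of one simulated stimulation session.

    The default protocol mirrors the manual experiment: ~5 min baseline,
    a stepped amplitude ramp of 1 mA roughly every 10 s during
    stimulation, ~30 s continued stimulation once the response threshold
    is reached, and up to 10 min of post-stimulation recording.
    """

    sample_rate: float = 50.0
    before_duration: float = 300.0
    max_during_duration: float = 600.0
    after_duration: float = 600.0
    ramp_step: float = 1.0
    ramp_dwell: float = 10.0
    hold_duration: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate < 25.0:
            raise ConfigurationError("sample_rate must be >= 25 Hz (Nyquist for 12 Hz tremor)")
        if min(self.before_duration, self.max_during_duration, self.after_duration) < 0:
            raise ConfigurationError("durations must be >= 0")
        if self.ramp_step <= 0 or self.ramp_dwell <= 0:
            raise ConfigurationError("ramp_step and ramp_dwell must be positive")


@dataclass
class GyroStream:
    """A uniformly sampled 3-axis gyroscope log with the applied stimulation.

    Attributes
    ----------
    timestamps : np.ndarray
        Seconds from session start, strictly increasing, uniform spacing.
    g_x, g_y, g_z : np.ndarray
        Angular-velocity samples per axis (gyro units).
    i_t : np.ndarray
        Applied pulse amplitude (mA) per sample; 0 outside stimulation.
    section : np.ndarray
        Per-sample section label: ``before`` / ``during`` / ``after``.
    """

    timestamps: np.ndarray
    g_x: np.ndarray
    g_y: np.ndarray
    g_z: np.ndarray
    i_t: np.ndarray
    section: np.ndarray
    sample_rate: float
    patient_id: str = "anon"

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        for name in ("g_x", "g_y", "g_z", "i_t", "section"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length differs from timestamps")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        outside = self.section != SECTION_DURING
        if np.any(self.i_t[outside] != 0):
            raise ValueError("i_t must be 0 outside the during-stimulation section")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    """Rejection-sampled truncated normal; robust for the mild truncations used here."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = (out < lo) | (out > hi)
    return out


def _lognormal_from_moments(rng: np.random.Generator, mean: float, sd: float) -> float:
    # match arithmetic mean/SD of the target (right-skewed) distribution
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def generate_patient(seed: int, settings: CohortSettings | None = None, patient_id: str | None = None) -> PatientProfile:
    """Draw one virtual patient profile deterministically from ``seed``."""
    settings = settings or CohortSettings()
    rng = np.random.default_rng(seed)
    freq = _truncated_normal(rng, settings.freq_mean, settings.freq_sd, *settings.freq_bounds, size=3)
    rms = np.array(
        [
            np.clip(
                _lognormal_from_moments(rng, m, s),
                settings.rms_bounds[0],
                settings.rms_bounds[1],
            )
            for m, s in zip(settings.rms_mean, settings.rms_sd)
        ]
    )
    threshold = float(
        _truncated_normal(
            rng, settings.threshold_mean, settings.threshold_sd, *settings.threshold_bounds
        )
    )
    floor = float(rng.uniform(*settings.floor_bounds))
    hold = float(
        np.clip(
            settings.hold_median * np.exp(rng.normal(0.0, settings.hold_log_sd)),
            settings.hold_bounds[0],
            settings.hold_bounds[1],
        )
    )
    ramp = float(rng.uniform(*settings.ramp_bounds))
    noise_sd = float(rng.uniform(*settings.noise_frac_bounds) * np.mean(rms))
    return PatientProfile(
        patient_id=patient_id or f"P{seed:04d}",
        tremor_freq=freq,
        baseline_rms=rms,
        response_threshold=threshold,
        suppression_floor=floor,
        reset_hold=hold,
        reemergence_ramp=ramp,
        noise_sd=noise_sd,
    )


def generate_cohort(n_patients: int, seed: int, settings: CohortSettings | None = None) -> list[PatientProfile]:
    """Draw ``n_patients`` profiles; per-patient seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_patients)]
    return [
        generate_patient(cs, settings, patient_id=f"P{i:03d}")
        for i, cs in enumerate(child_seeds)
    ]


def auto_ramp_schedule(profile: PatientProfile, config: SessionConfig) -> np.ndarray:
    """Stepped manual protocol as a per-second amplitude schedule (mA).

    Amplitude starts at ``ramp_step`` and rises by ``ramp_step`` every
    ``ramp_dwell`` seconds until it reaches the patient's response
    threshold, is then held for ``hold_duration`` seconds, and switches
    off. Truncated at ``max_during_duration``.
    """
    target = float(np.ceil(profile.response_threshold / config.ramp_step) * config.ramp_step)
    amps = []
    amp = config.ramp_step
    while amp < target and len(amps) < config.max_during_duration:
        amps.extend([amp] * int(config.ramp_dwell))
        amp += config.ramp_step
    amps.extend([min(amp, target)] * int(config.hold_duration))
    amps = amps[: int(config.max_during_duration)]
    return np.asarray(amps, dtype=float)


def _envelope(i_t: np.ndarray, dt: float, profile: PatientProfile) -> np.ndarray:
    """Forward-simulate the tremor amplitude multiplier per sample.

    Piecewise dynamics: slew from 1 toward ``suppression_floor`` over
    ``TRANSITION_S`` while the applied amplitude is at or above the
    response threshold; after withdrawal hold the floor for
    ``reset_hold`` seconds, then ramp linearly back to 1 over
    ``reemergence_ramp`` seconds.
    """
    floor = profile.suppression_floor
    down_rate = (1.0 - floor) / TRANSITION_S
    up_rate = np.inf if profile.reemergence_ramp == 0 else (1.0 - floor) / profile.reemergence_ramp
    env = np.empty_like(i_t, dtype=float)
    e = 1.0
    off_timer = 0.0
    for k, amp in enumerate(i_t):
        if amp >= profile.response_threshold:
            e = max(floor, e - down_rate * dt)
            off_timer = 0.0
        elif e < 1.0:
            off_timer += dt
            if off_timer >= profile.reset_hold:
                e = min(1.0, e + up_rate * dt) if np.isfinite(up_rate) else 1.0
        env[k] = e
    return env


def simulate_session(
    profile: PatientProfile,
    config: SessionConfig | None = None,
    protocol: str | np.ndarray = "auto_ramp",
) -> GyroStream:
    """Simulate a full before/during/after stimulation session.

    ``protocol`` is either ``"auto_ramp"`` (stepped manual protocol, see
    :func:`auto_ramp_schedule`) or an explicit per-second amplitude
    schedule for the during-stimulation section.
    """
    config = config or SessionConfig()
    if isinstance(protocol, str):
        if protocol != "auto_ramp":
            raise ConfigurationError(f"unknown protocol {protocol!r}")
        schedule = auto_ramp_schedule(profile, config)
    else:
        schedule = np.asarray(protocol, dtype=float)
        if schedule.size > config.max_during_duration:
            raise ConfigurationError("explicit schedule longer than max_during_duration")
        if np.any(schedule < 0):
            raise ConfigurationError("schedule amplitudes must be >= 0")

    sr = config.sample_rate
    n_before = int(round(config.before_duration * sr))
    n_during = int(len(schedule) * sr)  # schedule is per-second
    n_after = int(round(config.after_duration * sr))
    n = n_before + n_during + n_after

    t = np.arange(n) / sr
    i_t = np.zeros(n)
    if n_during:
        i_t[n_before : n_before + n_during] = np.repeat(schedule, int(sr))
    section = np.empty(n, dtype=object)
    section[:n_before] = SECTION_BEFORE
    section[n_before : n_before + n_during] = SECTION_DURING
    section[n_before + n_during :] = SECTION_AFTER

    env = _envelope(i_t, 1.0 / sr, profile)
    rng = np.random.default_rng(config.seed)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    amps = profile.baseline_rms * np.sqrt(2.0)
    axes = []
    for ax in range(3):
        sig = env * amps[ax] * np.sin(2 * np.pi * profile.tremor_freq[ax] * t + phases[ax])
        if profile.noise_sd > 0:
            sig = sig + rng.normal(0.0, profile.noise_sd, size=n)
        axes.append(sig)

    return GyroStream(
        timestamps=t,
        g_x=axes[0],
        g_y=axes[1],
        g_z=axes[2],
        i_t=i_t,
        section=np.asarray(section),
        sample_rate=sr,
        patient_id=profile.patient_id,
    )


def expected_reset_summary(profile: PatientProfile, config: SessionConfig | None = None) -> dict:
    """Closed-form ground truth for the reset-time metric on an auto-ramp session.

    Noise-free expectations, in seconds, against which the windowed
    pipeline estimate can be checked:

    * suppression onset: the envelope crosses 50 % of baseline a fixed
      fraction of the slew interval after the amplitude first reaches
      the response threshold;
    * ``B``: suppressed time within the during section;
    * ``C``: ``reset_hold`` plus the portion of the linear re-emergence
      ramp below the 50 % reduction threshold;
    * ``D = B + C``.
    """
    config = config or SessionConfig()
    schedule = auto_ramp_schedule(profile, config)
    floor = profile.suppression_floor
    n_steps_to_threshold = int(np.argmax(schedule >= profile.response_threshold))
    t_thresh = float(n_steps_to_threshold)  # seconds into the during section
    t_cross_down = t_thresh + 0.5 * TRANSITION_S / (1.0 - floor)
    a = float(len(schedule))
    b = a - t_cross_down
    c = profile.reset_hold + (0.5 - floor) / (1.0 - floor) * profile.reemergence_ramp
    return {
        "stim_duration_A": a,
        "reduction_during_B": b,
        "continuing_after_C": c,
        "reset_time_D": b + c,
        "suppression_onset_s": config.before_duration + t_cross_down,
    }


# ---------------------------------------------------------------------------
# CSV round trip (glove cloud-log format)
# ---------------------------------------------------------------------------

GLOVE_COLUMNS = ["timestamp", "gx", "gy", "gz", "pulse_amplitude_mA", "section"]


def write_glove_csv(stream: GyroStream, path) -> None:
    """Write a stream in the glove log dialect (comma-separated, header, UTF-8)."""
    df = pd.DataFrame(
        {
            "timestamp": stream.timestamps,
            "gx": stream.g_x,
            "gy": stream.g_y,
            "gz": stream.g_z,
            "pulse_amplitude_mA": stream.i_t,
            "section": stream.section,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_glove_csv(path, sample_rate: float | None = None, patient_id: str | None = None) -> GyroStream:
    """Read a glove CSV log back into a :class:`GyroStream`.

    Raises :class:`GloveCsvError` with a 1-based line number for missing
    columns, non-numeric rows, or non-monotone timestamps.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise GloveCsvError(f"{path}: unparseable CSV ({exc})") from exc
    missing = [c for c in GLOVE_COLUMNS if c not in df.columns]
    if missing:
        raise GloveCsvError(f"{path}: missing columns {missing}")
    numeric = df[GLOVE_COLUMNS[:-1]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        line = int(np.argmax(bad.to_numpy())) + 2  # +1 header, +1 1-based
        raise GloveCsvError(f"{path}: malformed numeric value at line {line}")
    ts = numeric["timestamp"].to_numpy()
    if len(ts) > 1:
        nonmono = np.diff(ts) <= 0
        if nonmono.any():
            line = int(np.argmax(nonmono)) + 3  # offending (second) row, 1-based
            raise GloveCsvError(f"{path}: non-monotone timestamp at line {line}")
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(ts))) if len(ts) > 1 else 1.0
    return GyroStream(
        timestamps=ts,
        g_x=numeric["gx"].to_numpy(),
        g_y=numeric["gy"].to_numpy(),
        g_z=numeric["gz"].to_numpy(),
        i_t=numeric["pulse_amplitude_mA"].to_numpy(),
        section=df["section"].to_numpy(),
        sample_rate=float(round(sample_rate, 6)),
        patient_id=patient_id or "anon",
    )


# ---------------------------------------------------------------------------
# Learning-sanity benchmark cohort
# ---------------------------------------------------------------------------

def make_band_rule_cohort(
    n_patients: int = 12,
    n_windows: int = 300,
    seed: int = 0,
    noise_sd: float = 0.4,
    dwell: int = 15,
) -> pd.DataFrame:
    """Labelled records where the class follows deterministically from an
    RMS band and the previous stimulation level.

    Emulates the physician's gradual adjustment: a hidden desired level
    walks up and down 0..4 (``dwell`` windows per step); each window's
    gyroscope RMS falls into a low / mid / high band encoding "step
    down" / "hold" / "step up", and the target class is
    ``clip(prev + direction, 0, 4)``. The class is therefore a
    deterministic function of the RMS band and the previous level, and is
    deliberately ambiguous given the gyroscope features alone.

    Returns a records DataFrame with columns ``patient_id, window_index,
    rms_x, rms_y, rms_z, prev_class, target_class``.
    """
    rng = np.random.default_rng(seed)
    band_centers = {-1: 1.0, 0: 3.5, 1: 6.5}
    rows = []
    for p in range(n_patients):
        path = list(range(5)) + list(range(3, 0, -1))  # 0..4..1, cycled
        desired = np.repeat(np.tile(path, n_windows // (len(path) * dwell) + 1), dwell)[:n_windows]
        prev = 0
        for w in range(n_windows):
            direction = int(np.sign(desired[w] - prev))
            target = int(np.clip(prev + direction, 0, 4))
            rx = band_centers[direction] + rng.normal(0, noise_sd)
            ry = 0.6 * band_centers[direction] + rng.normal(0, noise_sd)
            rz = abs(rng.normal(0.5, noise_sd))
            rows.append(
                {
                    "patient_id": f"S{p:03d}",
                    "window_index": w,
                    "rms_x": rx,
                    "rms_y": ry,
                    "rms_z": rz,
                    "prev_class": prev,
                    "target_class": target,
                }
            )
            prev = target
    return pd.DataFrame(rows)


__all__ = [
    "PatientProfile",
    "CohortSettings",
    "SessionConfig",
    "GyroStream",
    "ConfigurationError",
    "GloveCsvError",
    "generate_patient",
    "generate_cohort",
    "auto_ramp_schedule",
    "simulate_session",
    "expected_reset_summary",
    "write_glove_csv",
    "read_glove_csv",
    "make_band_rule_cohort",
    "TRANSITION_S",
    "SECTION_BEFORE",
    "SECTION_DURING",
    "SECTION_AFTER",
]
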