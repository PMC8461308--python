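"""Windowed RMS features and dominant tremor frequency from gyroscope streams.

Raw angular-velocity samples are aggregated into contiguous,
non-overlapping 1-s windows (half-open intervals anchored at session
start); each window carries the per-axis RMS, the pulse amplitude applied
during the window, and the session section. The dominant tremor frequency
is the periodogram peak within a physiological band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from tremorkit.synthetic import GyroStream

FEATURE_COLUMNS = ["window_index", "rms_x", "rms_y", "rms_z", "i_t", "section"]


@dataclass(frozen=True)
class SpectrumEstimate:
    axis: str
    dominant_freq: float
    peak_power: float


def _modal_value(values: np.ndarray):
    """Most frequent value; ties broken toward the value occurring later."""
    uniq, inv = np.unique(values, return_inverse=True)
    counts = np.bincount(inv)
    best = counts.max()
    tied = set(np.nonzero(counts == best)[0])
    # scan from the end: first value whose index is tied wins
    for v_idx in inv[::-1]:
        if v_idx in tied:
            return uniq[v_idx]
    return uniq[0]  # pragma: no cover


def rms_windows(stream: GyroStream, window_s: float = 1.0) -> pd.DataFrame:
    """Aggregate a stream into per-window RMS features.

    Each window ``k`` covers the half-open interval ``[k*window_s,
    (k+1)*window_s)`` from session start; the per-axis RMS is
    ``sqrt(mean(x**2))`` over the samples in the window. The window's
    pulse amplitude and section label are the modal within-window values
    (ties broken toward the later sample — amplitude changes within a
    window are rare under the stepped 10-s protocol). A trailing partial
    window is dropped.
    """
    if len(stream) == 0:
        raise ValueError("empty stream")
    n_per = int(round(window_s * stream.sample_rate))
    if n_per < 2:
        raise ValueError("window_s * sample_rate must be >= 2 samples")
    n_win = len(stream) // n_per
    if n_win == 0:
        raise ValueError("stream shorter than one window")

    def _rms(x):
        x = x[: n_win * n_per].reshape(n_win, n_per)
        return np.sqrt(np.mean(x * x, axis=1))

    i_t = stream.i_t[: n_win * n_per].reshape(n_win, n_per)
    section = stream.section[: n_win * n_per].reshape(n_win, n_per)
    return pd.DataFrame(
        {
            "window_index": np.arange(n_win),
            "rms_x": _rms(stream.g_x),
            "rms_y": _rms(stream.g_y),
            "rms_z": _rms(stream.g_z),
            "i_t": [_modal_value(row) for row in i_t],
            "section": [_modal_value(row) for row in section],
        }
    )


def rms_magnitude(windows: pd.DataFrame | pd.Series) -> np.ndarray | float:
    """3-axis RMS magnitude ``sqrt(rms_x^2 + rms_y^2 + rms_z^2)`` per window."""
    if isinstance(windows, pd.Series):
        return float(np.sqrt(windows["rms_x"] ** 2 + windows["rms_y"] ** 2 + windows["rms_z"] ** 2))
    return np.sqrt(
        windows["rms_x"].to_numpy() ** 2
        + windows["rms_y"].to_numpy() ** 2
        + windows["rms_z"].to_numpy() ** 2
    )


def dominant_frequency(
    samples: np.ndarray,
    sample_rate: float,
    axis: str = "x",
    band: tuple[float, float] = (2.0, 12.0),
    resolution: float = 0.125,
) -> SpectrumEstimate:
    """Frequency of maximum periodogram power within ``band``.

    The segment must be at least 2 s long and sampled above twice the
    band's upper edge. Zero-padding brings the frequency-bin spacing to
    at most ``resolution`` Hz.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2 * sample_rate:
        raise ValueError("segment must be at least 2 s long")
    if sample_rate <= 2 * band[1]:
        raise ValueError("sample_rate must exceed twice the band upper edge")
    nfft = max(samples.size, int(np.ceil(sample_rate / resolution)))
    freqs, power = sp_signal.periodogram(samples, fs=sample_rate, nfft=nfft, detrend="constant")
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError("no frequency bins inside the search band")
    k = int(np.argmax(power[in_band]))
    return SpectrumEstimate(
        axis=axis,
        dominant_freq=float(freqs[in_band][k]),
        peak_power=float(power[in_band][k]),
    )


def write_features_csv(windows: pd.DataFrame, path) -> None:
    out = windows.rename(columns={"i_t": "pulse_amplitude_mA"})
    out.to_csv(path, index=False, float_format="%.6f")


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.rename(columns={"pulse_amplitude_mA": "i_t"})


__all__ = [
    "SpectrumEstimate",
    "FEATURE_COLUMNS",
    "rms_windows",
    "rms_magnitude",
    "dominant_frequency",
    "write_features_csv",
    "read_features_csv",
]
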