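"""Signal conditioning for the layer-1 variables.

Implements the per-channel pipeline applied before fuzzification: mains-hum
notch and Butterworth low-pass filtering (both zero-phase, so channels stay
time-aligned across the hierarchy), linear-interpolation resampling between
device rates, baseline-mean normalization with clipping to the 0-2 (cardiac)
or 1-2 (eye / electrodermal) ranges, windowed RMSSD from RR intervals, and
the categorical encodings (noise, difficulty, gaze events, humidity, task
counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "NormalizationSpec",
    "notch_filter",
    "butter_lowpass",
    "resample_uniform",
    "normalize_baseline",
    "compute_rmssd",
    "encode_noise",
    "encode_difficulty",
    "encode_gaze_event",
    "encode_humidity",
    "normalize_task_counts",
    "gaze_events_to_signal",
]

RANGE_CARDIAC = (0.0, 2.0)  # HR, ECG amplitude, HRV after baseline division
RANGE_EYE_EDA = (1.0, 2.0)  # pupil, gaze code, skin conductance

_NOISE_CODES = {"low": 0.0, "medium": 0.5, "high": 1.0}
_DIFFICULTY_CODES = {"low": 0.0, "medium": 0.5, "high": 1.0}
_GAZE_CODES = {"fixation": 2.0, "saccade": 1.0}


@dataclass(frozen=True)
class NormalizationSpec:
    """Baseline-division normalization with saturation to a fixed range."""

    baseline_mean: float
    out_range: tuple[float, float] = RANGE_CARDIAC
    clip: bool = True

    def __post_init__(self) -> None:
        if self.out_range not in (RANGE_CARDIAC, RANGE_EYE_EDA):
            raise ValueError("out_range must be (0, 2) or (1, 2)")
        if not np.isfinite(self.baseline_mean) or self.baseline_mean <= 0:
            raise ValueError("invalid baseline: mean must be finite and > 0")


def _zero_phase(sos: np.ndarray, x: np.ndarray, fs: float, bandwidth: float) -> np.ndarray:
    # Even-reflect pad over several filter time constants so the
    # forward-backward pass settles without injecting a boundary step;
    # crucial for the 0.05 Hz stage whose transient spans many seconds.
    x = np.asarray(x, dtype=float)
    padlen = min(x.size - 1, int(np.ceil(3.0 * fs / bandwidth)))
    return sps.sosfiltfilt(sos, x, padlen=padlen, padtype="even")


def notch_filter(x: Sequence[float], fs: float, f0: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at ``f0`` (mains hum); Q = f0 / bandwidth."""
    if fs <= 2.0 * f0:
        raise ValueError("notch above Nyquist: need fs > 2*f0")
    b, a = sps.iirnotch(f0, q, fs=fs)
    sos = sps.tf2sos(b, a)
    return _zero_phase(sos, x, fs, f0 / q)


def butter_lowpass(x: Sequence[float], fs: float, cutoff: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass (-3 dB of the designed filter at cutoff)."""
    if not 0 < cutoff < fs / 2.0:
        raise ValueError("cutoff must lie strictly below the Nyquist frequency")
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return _zero_phase(sos, x, fs, cutoff)


def resample_uniform(x: Sequence[float], fs_in: float, fs_out: float) -> np.ndarray:
    """Linear-interpolation resampling preserving duration within one period.

    Upsampling interpolates between samples; downsampling interpolates the
    already low-passed signal directly (the pipeline's 0.05-1 Hz filters act
    as the anti-alias stage).
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("cannot resample a single-sample signal")
    if fs_in == fs_out:
        return x.copy()
    t_in = np.arange(x.size) / fs_in
    n_out = int(round((x.size - 1) * fs_out / fs_in)) + 1
    t_out = np.arange(n_out) / fs_out
    return np.interp(t_out, t_in, x)


def normalize_baseline(x: Sequence[float], spec: NormalizationSpec) -> np.ndarray:
    """Divide by the baseline mean and saturate into ``spec.out_range``."""
    y = np.asarray(x, dtype=float) / spec.baseline_mean
    if spec.clip:
        y = np.clip(y, *spec.out_range)
    return y


def compute_rmssd(
    rr: Sequence[float], window: float = 30.0, step: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed RMSSD over an RR-interval series.

    ``rr`` are successive inter-beat intervals in milliseconds; interval ``i``
    onsets at the cumulative sum of the preceding intervals.  For each window
    ``[k*step, k*step + window)`` the RMSSD of the intervals whose onset falls
    inside is sqrt(mean(diff**2)); windows holding fewer than two intervals
    yield NaN.  Returns (window start times in s, RMSSD values in ms).
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least 2 RR intervals")
    onsets = np.concatenate([[0.0], np.cumsum(rr[:-1])]) / 1000.0
    total = float(onsets[-1])
    starts = np.arange(0.0, max(total - window, 0.0) + step / 2, step)
    if starts.size == 0:
        starts = np.array([0.0])
    values = np.full(starts.size, np.nan)
    for k, s in enumerate(starts):
        mask = (onsets >= s) & (onsets < s + window)
        seg = rr[mask]
        if seg.size >= 2:
            d = np.diff(seg)
            values[k] = np.sqrt(np.mean(d**2))
    return starts, values


def _encode(label: str, table: dict[str, float], what: str) -> float:
    try:
        return table[label]
    except KeyError:
        raise ValueError(
            f"unknown {what} label {label!r}; expected one of {sorted(table)}"
        ) from None


def encode_noise(label: str) -> float:
    """low -> 0, medium -> 0.5, high -> 1."""
    return _encode(label, _NOISE_CODES, "noise")


def encode_difficulty(label: str) -> float:
    """low -> 0, medium -> 0.5, high -> 1."""
    return _encode(label, _DIFFICULTY_CODES, "difficulty")


def encode_gaze_event(label: str) -> float:
    """fixation -> 2, saccade -> 1 (fixations read as higher load)."""
    return _encode(label, _GAZE_CODES, "gaze event")


def encode_humidity(h: float) -> float:
    """Relative humidity percent -> fraction in [0, 1]."""
    if not 0.0 <= h <= 100.0:
        raise ValueError("humidity must be in [0, 100] percent")
    return h / 100.0


def normalize_task_counts(values: Sequence[float]) -> np.ndarray:
    """Divide each count by the maximum observed value in the test."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.all(v == 0):
        raise ValueError("degenerate task table: all counts zero")
    if np.any(v < 0):
        raise ValueError("task counts must be non-negative")
    return v / v.max()


def gaze_events_to_signal(
    events: Sequence[tuple[float, str]], fs: float, duration: float, t0: float = 0.0
) -> np.ndarray:
    """Convert gaze events to a numeric step signal sampled at ``fs``.

    The signal holds the code of the most recent fixation/saccade event;
    labels outside that vocabulary hold the previous value (no artificial
    load transition), and samples before the first codable event hold its
    value.
    """
    n = int(round(duration * fs))
    codes: list[tuple[float, float]] = []
    last = None
    for t, lab in events:
        if lab in _GAZE_CODES:
            last = _GAZE_CODES[lab]
            codes.append((t - t0, last))
    if not codes:
        raise ValueError("gaze event channel holds no fixation/saccade events")
    times = np.array([t for t, _ in codes])
    vals = np.array([v for _, v in codes])
    t_grid = np.arange(n) / fs
    idx = np.searchsorted(times, t_grid, side="right") - 1
    idx = np.clip(idx, 0, len(vals) - 1)
    return vals[idx]
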