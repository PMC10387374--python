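"""Fiber-photometry signal processing.

The pipeline follows the standard isosbestic-control workflow for dual-channel
recordings: the 405 nm control channel (calcium-independent, so it carries
shared artifacts such as photobleaching and motion but no neural transients)
is downsampled to 60 Hz, low-pass filtered, upsampled back to the acquisition
rate, fitted to the 490 nm GCaMP channel by affine least squares, and
subtracted to give ΔF. %ΔF/F divides by the session-mean fluorescence minus
the rig baseline measured without the animal, and z-scoring uses the window
from the first trial start to 10 s after the last trial end.

Choices the workflow leaves open are frozen here: the low-pass filter is a
zero-phase second-order Butterworth with 2 Hz cutoff applied at the 60 Hz
intermediate rate; resampling is polyphase; the control fit has both gain and
offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

LOWPASS_ORDER = 2
LOWPASS_CUTOFF_HZ = 2.0
INTERMEDIATE_FS = 60.0
POST_TRIAL_PAD_S = 10.0


@dataclass
class PhotometryRecord:
    """Dual-channel photometry trace with trial events and rig baseline."""

    signal_490: np.ndarray
    control_405: np.ndarray
    fs: float  # acquisition sampling rate, Hz (typically ~1017)
    trial_event_times: np.ndarray | None = None  # seconds
    rig_baseline_F: float = 0.0

    def __post_init__(self) -> None:
        self.signal_490 = np.asarray(self.signal_490, float)
        self.control_405 = np.asarray(self.control_405, float)
        if self.signal_490.shape != self.control_405.shape:
            raise ValueError("signal and control lengths differ")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.rig_baseline_F < 0:
            raise ValueError("rig_baseline_F must be nonnegative")


def _resample_to(x: np.ndarray, fs_in: float, fs_out: float, n_out: int | None = None):
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    y = signal.resample_poly(x, frac.numerator, frac.denominator, padtype="line")
    if n_out is not None:
        if len(y) >= n_out:
            y = y[:n_out]
        else:
            y = np.pad(y, (0, n_out - len(y)), mode="edge")
    return y


def smooth_control(control: np.ndarray, fs: float) -> np.ndarray:
    """Downsample the control channel to 60 Hz, low-pass, and upsample back."""
    n = len(control)
    # center first: the chain is linear, so removing/restoring the mean makes
    # it exactly affine-equivariant (constants pass through untouched)
    m = float(np.mean(control))
    down = _resample_to(control - m, fs, INTERMEDIATE_FS)
    sos = signal.butter(
        LOWPASS_ORDER, LOWPASS_CUTOFF_HZ, fs=INTERMEDIATE_FS, output="sos"
    )
    filt = signal.sosfiltfilt(sos, down)
    return _resample_to(filt, INTERMEDIATE_FS, fs, n_out=n) + m


def control_correct(record: PhotometryRecord) -> np.ndarray:
    """ΔF: GCaMP signal minus the fitted, smoothed control channel.

    The smoothed control is fitted to the signal by affine least squares
    (gain + offset), so the correction is invariant to affine rescaling of
    the control channel.
    """
    if len(record.signal_490) < int(2 * record.fs):
        raise ValueError("need at least 2 s of data")
    smoothed = smooth_control(record.control_405, record.fs)
    X = np.column_stack([smoothed, np.ones_like(smoothed)])
    coef, *_ = np.linalg.lstsq(X, record.signal_490, rcond=None)
    fitted = X @ coef
    return record.signal_490 - fitted


def dff(delta_f: np.ndarray, rig_baseline_F: float, session_mean_F: float) -> np.ndarray:
    """%ΔF/F with denominator (session mean F) - (rig baseline F)."""
    denom = session_mean_F - rig_baseline_F
    if denom <= 0:
        raise ValueError("session mean must exceed rig baseline")
    return 100.0 * np.asarray(delta_f, float) / denom


def zscore_session(
    series: np.ndarray,
    fs: float,
    first_trial_start: float,
    last_trial_end: float,
) -> np.ndarray:
    """Z-score the full series using statistics from the behavioural window.

    The mean and SD are computed on [first_trial_start, last_trial_end + 10 s]
    (clipped to the recording) and applied to every sample.
    """
    series = np.asarray(series, float)
    i0 = max(0, int(round(first_trial_start * fs)))
    i1 = min(len(series), int(round((last_trial_end + POST_TRIAL_PAD_S) * fs)))
    if i1 <= i0:
        raise ValueError("z-scoring window lies outside the recording")
    window = series[i0:i1]
    sd = window.std()
    if sd == 0:
        raise ValueError("zero standard deviation in the z-scoring window")
    return (series - window.mean()) / sd


def process(record: PhotometryRecord) -> dict:
    """Full chain: control correction -> %ΔF/F -> session z-score."""
    delta_f = control_correct(record)
    out = {"delta_f": delta_f}
    session_mean = float(record.signal_490.mean())
    out["dff"] = dff(delta_f, record.rig_baseline_F, session_mean)
    if record.trial_event_times is not None and len(record.trial_event_times):
        out["zscore"] = zscore_session(
            delta_f,
            record.fs,
            float(np.min(record.trial_event_times)),
            float(np.max(record.trial_event_times)),
        )
    return out


def align_trials(
    series: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    window: tuple = (-2.0, 8.0),
) -> np.ndarray:
    """Event-aligned trial matrix (n_events, n_samples) for a processed trace."""
    pre = int(round(-window[0] * fs))
    post = int(round(window[1] * fs))
    rows = []
    for t in np.asarray(event_times, float):
        c = int(round(t * fs))
        if c - pre < 0 or c + post > len(series):
            continue
        rows.append(series[c - pre : c + post])
    return np.array(rows)
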