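"""sEMG preprocessing and windowed time-domain feature extraction.

Preprocessing is a 3rd-order Butterworth high-pass with a 20 Hz break
frequency, which removes baseline drift and motion artifact while leaving
the EMG power band (~20-450 Hz) intact.  Causal filtering (``lfilter``)
mirrors real-time operation; zero-phase (``filtfilt``) is available for
offline analysis.

Each sliding window is summarised per channel by the four classic
time-domain features:

* MAV  — mean absolute value, ``(1/N) * sum |x_i|``
* CL   — curve (waveform) length, ``sum |x_i - x_{i-1}|`` (unnormalized)
* ZC   — zero crossings, sign changes with an amplitude deadband
* SSC  — slope sign changes, local extrema with an amplitude deadband

Feature columns are channel-major: ``ch0_MAV, ch0_CL, ch0_ZC, ch0_SSC,
ch1_MAV, ...`` for C channels, giving ``C * 4`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal as sps

from .core import UNLABELED, CueSchedule, EMGRecording, LabelStream

__all__ = [
    "FilterSpec",
    "FeatureConfig",
    "FeatureMatrix",
    "FEATURE_NAMES",
    "design_highpass",
    "apply_filter",
    "mav",
    "curve_length",
    "zero_crossings",
    "slope_sign_changes",
    "extract_features",
]

FEATURE_NAMES: tuple[str, ...] = ("MAV", "CL", "ZC", "SSC")


@dataclass(frozen=True)
class FilterSpec:
    """High-pass Butterworth specification (defaults: 3rd order, 20 Hz)."""

    order: int = 3
    cutoff_hz: float = 20.0
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")
        if not 0.0 < self.cutoff_hz < self.sample_rate / 2.0:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, Nyquist="
                f"{self.sample_rate / 2.0} Hz)"
            )


@dataclass(frozen=True)
class FeatureConfig:
    """Windowing and deadband configuration for feature extraction.

    The 100 ms stride matches the decoder's decision cadence; the 200 ms
    window is the usual bias/latency compromise for sEMG pattern
    recognition.  Deadband thresholds (mV) suppress noise-floor ZC/SSC
    counts; 0 disables the deadband.
    """

    window_ms: float = 200.0
    stride_ms: float = 100.0
    zc_threshold: float = 0.01
    ssc_threshold: float = 0.01

    def __post_init__(self) -> None:
        if not self.window_ms >= self.stride_ms > 0:
            raise ValueError(
                f"require window_ms >= stride_ms > 0, got "
                f"window={self.window_ms}, stride={self.stride_ms}"
            )
        if self.zc_threshold < 0 or self.ssc_threshold < 0:
            raise ValueError("deadband thresholds must be >= 0")


@dataclass
class FeatureMatrix:
    """Windowed features with per-window labels and window start times."""

    values: np.ndarray  # W x (C*4)
    window_starts: np.ndarray  # seconds
    labels: LabelStream
    n_channels: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.window_starts = np.asarray(self.window_starts, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (windows x features)")
        if self.values.shape[1] != self.n_channels * len(FEATURE_NAMES):
            raise ValueError(
                f"expected {self.n_channels * len(FEATURE_NAMES)} feature columns "
                f"for {self.n_channels} channels, got {self.values.shape[1]}"
            )
        if not (len(self.values) == len(self.window_starts) == len(self.labels)):
            raise ValueError("values, window_starts and labels must align")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def column_names(self) -> list[str]:
        return [
            f"ch{c}_{f}" for c in range(self.n_channels) for f in FEATURE_NAMES
        ]

    def labeled(self) -> "FeatureMatrix":
        """Subset of windows carrying a motion label (drops rest windows)."""
        keep = self.labels.labels != UNLABELED
        return FeatureMatrix(
            self.values[keep],
            self.window_starts[keep],
            LabelStream(self.labels.labels[keep]),
            self.n_channels,
        )


def design_highpass(spec: FilterSpec) -> tuple[np.ndarray, np.ndarray]:
    """Digital Butterworth high-pass coefficients ``(b, a)``.

    The magnitude response at the cutoff is 1/sqrt(2) of the passband gain
    (the -3 dB point), and the DC gain is zero.
    """
    return sps.butter(
        spec.order, spec.cutoff_hz, btype="highpass", fs=spec.sample_rate
    )


def apply_filter(
    rec: EMGRecording,
    spec: FilterSpec | None = None,
    mode: Literal["causal", "zero-phase"] = "causal",
) -> EMGRecording:
    """High-pass filter every channel of a recording.

    Causal mode introduces the filter's group delay, as in real-time
    operation; zero-phase mode filters forward and backward and does not.
    """
    if spec is None:
        spec = FilterSpec(sample_rate=rec.sample_rate)
    if rec.n_samples <= 3 * spec.order:
        raise ValueError(
            f"recording too short to filter: {rec.n_samples} samples, "
            f"need > {3 * spec.order}"
        )
    b, a = design_highpass(spec)
    if mode == "causal":
        out = sps.lfilter(b, a, rec.samples, axis=1)
    elif mode == "zero-phase":
        out = sps.filtfilt(b, a, rec.samples, axis=1)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return EMGRecording(out, rec.sample_rate, rec.start_time)


# ---------------------------------------------------------------------------
# Single-window features.  Each accepts a 1-D window in mV.
# ---------------------------------------------------------------------------

def mav(x: np.ndarray) -> float:
    """Mean absolute value of a window."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("mav requires a non-empty window")
    return float(np.mean(np.abs(x)))


def curve_length(x: np.ndarray) -> float:
    """Waveform length: sum of absolute successive differences."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("curve_length requires a window of length >= 2")
    return float(np.sum(np.abs(np.diff(x))))


def zero_crossings(x: np.ndarray, thresh: float = 0.0) -> int:
    """Count sign changes whose amplitude step clears the deadband.

    A crossing at i requires ``sign(x_i) != sign(x_{i-1})`` and
    ``|x_i - x_{i-1}| >= thresh``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("zero_crossings requires a window of length >= 2")
    if thresh < 0:
        raise ValueError("threshold must be >= 0")
    sign_change = np.sign(x[1:]) != np.sign(x[:-1])
    big_enough = np.abs(np.diff(x)) >= thresh
    return int(np.count_nonzero(sign_change & big_enough))


def slope_sign_changes(x: np.ndarray, thresh: float = 0.0) -> int:
    """Count local extrema whose larger adjacent step clears the deadband.

    An extremum at interior i requires ``(x_i - x_{i-1}) * (x_i - x_{i+1}) > 0``
    and ``max(|x_i - x_{i-1}|, |x_i - x_{i+1}|) >= thresh``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError("slope_sign_changes requires a window of length >= 3")
    if thresh < 0:
        raise ValueError("threshold must be >= 0")
    dl = x[1:-1] - x[:-2]   # step up to i
    dr = x[1:-1] - x[2:]    # step down from i
    is_extremum = dl * dr > 0
    big_enough = np.maximum(np.abs(dl), np.abs(dr)) >= thresh
    return int(np.count_nonzero(is_extremum & big_enough))


# ---------------------------------------------------------------------------
# Windowed extraction
# ---------------------------------------------------------------------------

def extract_features(
    rec: EMGRecording,
    labels: CueSchedule | LabelStream | None = None,
    cfg: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Slide a window across the recording and compute the four features.

    Windows start at multiples of the stride; a recording of T samples
    yields ``floor((T - window) / stride) + 1`` windows.  Each window's
    label is taken from the cue covering its center (per-sample
    LabelStreams are read at the center sample); windows with no cue get
    ``UNLABELED``.
    """
    if cfg is None:
        cfg = FeatureConfig()
    win_n = int(round(cfg.window_ms * rec.sample_rate / 1000.0))
    stride_n = int(round(cfg.stride_ms * rec.sample_rate / 1000.0))
    if win_n < 3:
        raise ValueError("window too short for feature computation (need >= 3 samples)")
    if rec.n_samples < win_n:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{win_n}-sample window"
        )
    n_win = (rec.n_samples - win_n) // stride_n + 1
    starts_n = np.arange(n_win) * stride_n

    # Vectorized across windows: view of shape (C, n_win, win_n).
    windows = np.lib.stride_tricks.sliding_window_view(rec.samples, win_n, axis=1)
    windows = windows[:, starts_n, :]

    mav_v = np.mean(np.abs(windows), axis=2)                       # C x W
    cl_v = np.sum(np.abs(np.diff(windows, axis=2)), axis=2)        # C x W
    d = np.diff(windows, axis=2)
    zc_v = np.sum(
        (np.sign(windows[:, :, 1:]) != np.sign(windows[:, :, :-1]))
        & (np.abs(d) >= cfg.zc_threshold),
        axis=2,
    )
    dl = windows[:, :, 1:-1] - windows[:, :, :-2]
    dr = windows[:, :, 1:-1] - windows[:, :, 2:]
    ssc_v = np.sum(
        (dl * dr > 0) & (np.maximum(np.abs(dl), np.abs(dr)) >= cfg.ssc_threshold),
        axis=2,
    )

    values = np.empty((n_win, rec.n_channels * 4))
    values[:, 0::4] = mav_v.T
    values[:, 1::4] = cl_v.T
    values[:, 2::4] = zc_v.T
    values[:, 3::4] = ssc_v.T

    starts_s = rec.start_time + starts_n / rec.sample_rate
    centers_s = starts_s + cfg.window_ms / 2000.0

    if labels is None:
        lab = np.full(n_win, UNLABELED, dtype=np.int64)
    elif isinstance(labels, CueSchedule):
        lab = np.array([labels.label_at(t) for t in centers_s], dtype=np.int64)
    elif isinstance(labels, LabelStream):
        if len(labels) != rec.n_samples:
            raise ValueError(
                f"per-sample label stream length {len(labels)} does not match "
                f"recording length {rec.n_samples}"
            )
        center_idx = starts_n + win_n // 2
        lab = labels.labels[center_idx]
    else:
        raise TypeError(f"unsupported label source: {type(labels).__name__}")

    return FeatureMatrix(values, starts_s, LabelStream(lab), rec.n_channels)
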