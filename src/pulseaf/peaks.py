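"""Beat detection with two event-related moving averages.

A short moving average (window ~ one QRS complex / systolic upstroke) is
compared against a long one (window ~ one full heartbeat). Regions where the
short average exceeds the long one form "blocks of interest"; blocks narrower
than the expected peak width are rejected as noise, and the apex of each
surviving block is taken as the beat location. The PPG variant squares the
signal first so the systolic peak dominates the diastolic peak and dicrotic
notch; the ECG variant does not.

Expected sampling rate is the pipeline working rate (>= 50 Hz); below that
the short window collapses to under 3 samples and detection is refused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import InsufficientDataError, ParameterError
from .io_formats import Signal

__all__ = [
    "PeakDetectConfig",
    "ECG_PEAK_CONFIG",
    "PPG_PEAK_CONFIG",
    "PeakList",
    "RRSeries",
    "moving_average",
    "detect_peaks",
    "peaks_to_rr",
]


@dataclass(frozen=True)
class PeakDetectConfig:
    """Parameters of the two-moving-average detector.

    ``w1_ms`` is the expected peak duration (QRS ~100 ms, systolic wave
    ~111 ms), ``w2_ms`` the expected beat duration (ECG 525 ms, PPG 667 ms).
    The width threshold for accepting a block is ``w1 + beta`` (in samples
    after ms->sample conversion).
    """

    w1_ms: float = 100.0
    w2_ms: float = 525.0
    beta_ms: float = 0.0
    squaring: bool = False
    clip_negatives: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.w1_ms < self.w2_ms:
            raise ParameterError("need 0 < w1_ms < w2_ms")
        if self.beta_ms < -self.w1_ms:
            raise ParameterError("beta_ms must be >= -w1_ms")


ECG_PEAK_CONFIG = PeakDetectConfig(w1_ms=100.0, w2_ms=525.0, squaring=False)
PPG_PEAK_CONFIG = PeakDetectConfig(w1_ms=111.0, w2_ms=667.0, squaring=True)

CONFIG_BY_MODALITY = {"ecg": ECG_PEAK_CONFIG, "ppg": PPG_PEAK_CONFIG}


@dataclass
class PeakList:
    """Detected beats: 0-based sample indices, times (ms) and amplitudes."""

    indices: np.ndarray
    times_ms: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not (len(self.indices) == len(self.times_ms) == len(self.amplitudes)):
            raise ParameterError("peak list fields must have equal length")
        if len(self.indices) > 1 and not np.all(np.diff(self.indices) > 0):
            raise ParameterError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class RRSeries:
    """Successive inter-beat intervals in milliseconds."""

    intervals_ms: np.ndarray

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if np.any(self.intervals_ms <= 0):
            raise ParameterError("RR intervals must be positive")

    @property
    def n(self) -> int:
        return int(self.intervals_ms.size)

    def __len__(self) -> int:
        return self.n


def _odd_window(samples: float) -> int:
    w = int(round(samples))
    return w + 1 if w % 2 == 0 else w


def moving_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving mean with reflection padding at the edges.

    Even windows are adjusted up by one (with a warning) to stay centered.
    """
    x = np.asarray(x, dtype=float)
    if window_samples < 1:
        raise ParameterError("window must be >= 1 sample")
    if window_samples > x.size:
        raise ParameterError("window larger than the signal")
    if window_samples % 2 == 0:
        warnings.warn(
            f"even window {window_samples} adjusted to {window_samples + 1}",
            stacklevel=2,
        )
        window_samples += 1
    if window_samples == 1:
        return x.copy()
    return uniform_filter1d(x, size=window_samples, mode="reflect")


def detect_peaks(sig: Signal, config: PeakDetectConfig | None = None) -> PeakList:
    """Run the two-moving-average block detector on a filtered signal.

    Steps: optional clipping of negative samples to 0; optional element-wise
    squaring (PPG variant only); compute MA_peak (window W1) and MA_beat
    (window W2, both forced odd); mark blocks where MA_peak > MA_beat; reject
    blocks narrower than ``alpha = W1 + beta`` samples; within each surviving
    block take the argmax of the *original filtered* signal (earliest index on
    ties) as the beat.
    """
    if config is None:
        config = CONFIG_BY_MODALITY[sig.modality]
    w1 = _odd_window(config.w1_ms * sig.fs / 1000.0)
    w2 = _odd_window(config.w2_ms * sig.fs / 1000.0)
    if int(round(config.w1_ms * sig.fs / 1000.0)) < 3:
        raise ParameterError(
            f"sampling rate {sig.fs} Hz too low for W1={config.w1_ms} ms "
            "(minimum working rate is 50 Hz)"
        )
    if w2 > sig.n:
        raise ParameterError("signal shorter than the beat window W2")

    y = sig.samples
    if config.clip_negatives:
        y = np.maximum(y, 0.0)
    if config.squaring:
        y = y * y

    ma_peak = moving_average(y, w1)
    ma_beat = moving_average(y, w2)
    mask = ma_peak > ma_beat

    alpha = w1 + int(round(config.beta_ms * sig.fs / 1000.0))
    # numerical guard: in exact arithmetic the two averages tie on silent
    # stretches, but template tails at denormal scale can open junk blocks;
    # a relative amplitude floor removes them without breaking scale invariance
    amp_floor = 1e-10 * float(y.max(initial=0.0))

    # contiguous runs of the boolean mask
    edges = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if mask.size and mask[0]:
        starts = np.concatenate([[0], starts])
    if mask.size and mask[-1]:
        ends = np.concatenate([ends, [mask.size]])

    indices = []
    for s, e in zip(starts, ends):
        if e - s < alpha:
            continue  # block narrower than the expected peak width: noise
        if y[s:e].max() <= amp_floor:
            continue
        if s == 0 or e == mask.size:
            # blocks touching the record boundary are dominated by filter and
            # moving-average edge transients; a beat there is unreliable
            continue
        indices.append(s + int(np.argmax(sig.samples[s:e])))
    indices = np.asarray(indices, dtype=int)
    return PeakList(
        indices=indices,
        times_ms=sig.t0_ms + 1000.0 * indices / sig.fs,
        amplitudes=sig.samples[indices] if indices.size else np.array([]),
    )


def peaks_to_rr(peaks: PeakList) -> RRSeries:
    """Successive peak-time differences in milliseconds (N = peaks - 1)."""
    if len(peaks) < 2:
        raise InsufficientDataError(
            f"need at least 2 peaks to form intervals, got {len(peaks)}"
        )
    return RRSeries(np.diff(peaks.times_ms))
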