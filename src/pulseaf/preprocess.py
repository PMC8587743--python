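"""Bandpass filtering, FFT resampling and z-score normalization.

ECG strips are bandpassed at 8-20 Hz (2nd-order Butterworth), which removes
baseline drift and de-emphasizes P/T waves while keeping QRS energy; PPG uses
0.5-8 Hz (3rd order). Filtering is applied forward-backward (zero phase) so
peak *times*, which feed the HRV features, are not shifted. All signals are
then FFT-resampled to a common working rate (50 Hz by default).

Feature matrices are standardized column-wise to zero mean and unit sample
standard deviation (n-1 denominator). The scaler follows the scikit-learn
transformer protocol so it composes with sklearn pipelines; stats are fit on
a declared fitting partition and applied elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ParameterError
from .io_formats import Signal

__all__ = [
    "FilterSpec",
    "ECG_FILTER",
    "PPG_FILTER",
    "WORKING_FS",
    "bandpass_filter",
    "resample_fft",
    "ZScoreScaler",
    "NormalizationStats",
    "zscore_fit",
    "zscore_apply",
]

#: common working rate after resampling, Hz
WORKING_FS = 50.0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass specification."""

    order: int
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")
        if not 0 < self.low_hz < self.high_hz:
            raise ParameterError("need 0 < low_hz < high_hz")

    def validate_for(self, fs: float) -> None:
        if self.high_hz >= fs / 2:
            raise ParameterError(
                f"high cutoff {self.high_hz} Hz >= Nyquist ({fs / 2} Hz)"
            )


ECG_FILTER = FilterSpec(order=2, low_hz=8.0, high_hz=20.0)
PPG_FILTER = FilterSpec(order=3, low_hz=0.5, high_hz=8.0)

FILTER_BY_MODALITY = {"ecg": ECG_FILTER, "ppg": PPG_FILTER}


def bandpass_filter(sig: Signal, spec: FilterSpec | None = None) -> Signal:
    """Zero-phase Butterworth bandpass; length and fs are unchanged.

    When ``spec`` is omitted the modality's default band is used.
    """
    if spec is None:
        spec = FILTER_BY_MODALITY[sig.modality]
    spec.validate_for(sig.fs)
    sos = sps.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=sig.fs,
        output="sos",
    )
    filtered = sps.sosfiltfilt(sos, sig.samples)
    return Signal(filtered, fs=sig.fs, modality=sig.modality, t0_ms=sig.t0_ms)


def resample_fft(sig: Signal, target_fs: float) -> Signal:
    """Fourier-domain resampling to ``target_fs``.

    Output length is ``round(n * target_fs / fs)``. Upsampling is allowed but
    warned about, since the pipeline is designed around downsampling to the
    working rate.
    """
    if target_fs <= 0:
        raise ParameterError("target_fs must be positive")
    if sig.n < 2:
        raise ParameterError("cannot resample a signal shorter than 2 samples")
    if target_fs > sig.fs:
        warnings.warn(
            f"upsampling {sig.fs} Hz -> {target_fs} Hz", stacklevel=2
        )
    n_out = int(round(sig.n * target_fs / sig.fs))
    resampled = sps.resample(sig.samples, n_out)
    return Signal(resampled, fs=target_fs, modality=sig.modality, t0_ms=sig.t0_ms)


# --------------------------------------------------------------------------
# Feature standardization
# --------------------------------------------------------------------------

@dataclass
class NormalizationStats:
    """Per-feature mean and sample standard deviation (fixed feature order)."""

    mean: np.ndarray
    sd: np.ndarray


class ZScoreScaler(TransformerMixin, BaseEstimator):
    """Column-wise z-scoring with the sample (n-1) standard deviation.

    Unlike :class:`sklearn.preprocessing.StandardScaler` (population sd) this
    uses the n-1 denominator, matching the convention of the SDRR feature.
    Constant columns get sd replaced by 1 with a warning so they map to zeros.

    Parameters
    ----------
    expected_features : int or None
        If set, ``fit`` raises unless the matrix has this many columns
        (the HRV pipeline always produces 12).
    """

    def __init__(self, expected_features: int | None = None):
        self.expected_features = expected_features

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ParameterError("fit requires a 2-D matrix with >= 2 rows")
        if not np.all(np.isfinite(X)):
            raise ParameterError("feature matrix contains non-finite entries")
        if self.expected_features is not None and X.shape[1] != self.expected_features:
            raise ParameterError(
                f"expected {self.expected_features} feature columns, got {X.shape[1]}"
            )
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        constant = sd == 0
        if np.any(constant):
            warnings.warn(
                f"{int(constant.sum())} constant feature column(s); sd set to 1",
                stacklevel=2,
            )
            sd = np.where(constant, 1.0, sd)
        self.sd_ = sd
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ParameterError(
                f"expected {self.n_features_in_} columns, got {X.shape[1]}"
            )
        return (X - self.mean_) / self.sd_

    @property
    def stats_(self) -> NormalizationStats:
        return NormalizationStats(mean=self.mean_.copy(), sd=self.sd_.copy())


def zscore_fit(features: np.ndarray, expected_features: int | None = 12) -> NormalizationStats:
    """Fit normalization stats on a feature matrix (functional form)."""
    scaler = ZScoreScaler(expected_features=expected_features).fit(features)
    return scaler.stats_


def zscore_apply(features: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Apply previously fitted normalization stats."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] != stats.mean.shape[0]:
        raise ParameterError("feature/stats dimension mismatch")
    return (features - stats.mean) / stats.sd
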