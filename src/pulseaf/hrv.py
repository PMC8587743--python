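"""Time-domain HRV/PRV features from an RR-interval series.

Twelve statistics are computed per 30-s strip, in a fixed order shared with
the feature tables and the classifier input:

    meanRR, medianRR, madRR, mcvRR, SDRR, rMSSD,
    CVRR, CVSD, RR20, pRR20, RR50, pRR50

Definitions: rMSSD = sqrt(sum (RR_i - RR_{i+1})^2 / (N-1)); SDRR = sample
standard deviation (n-1 denominator); madRR = median(|RR - medianRR|)
(unscaled); mcvRR = madRR / medianRR; CVRR = SDRR / meanRR;
CVSD = rMSSD / meanRR; RR20/RR50 = counts of successive-difference magnitudes
strictly exceeding 20/50 ms, and pRR20/pRR50 their proportions over the total
number of intervals N (a flag allows the conventional N-1 denominator).

AF strips show markedly elevated rMSSD, CVRR and pRR50 relative to normal
sinus rhythm, which is the separation the downstream classifier exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .peaks import RRSeries

__all__ = [
    "FEATURE_NAMES",
    "HRVFeatureVector",
    "compute_rmssd",
    "compute_sdrr",
    "compute_features",
]

FEATURE_NAMES = (
    "meanRR", "medianRR", "madRR", "mcvRR", "SDRR", "rMSSD",
    "CVRR", "CVSD", "RR20", "pRR20", "RR50", "pRR50",
)

#: minimum number of intervals per strip for stable medians/differences
MIN_INTERVALS = 4


@dataclass(frozen=True)
class HRVFeatureVector:
    meanRR: float
    medianRR: float
    madRR: float
    mcvRR: float
    SDRR: float
    rMSSD: float
    CVRR: float
    CVSD: float
    RR20: float
    pRR20: float
    RR50: float
    pRR50: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "HRVFeatureVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(FEATURE_NAMES),):
            raise ParameterError(f"expected {len(FEATURE_NAMES)} features")
        return cls(**dict(zip(FEATURE_NAMES, arr)))


def _as_intervals(rr) -> np.ndarray:
    if isinstance(rr, RRSeries):
        return rr.intervals_ms
    return np.asarray(rr, dtype=float)


def compute_rmssd(rr) -> float:
    """Root mean square of successive RR differences, ms."""
    x = _as_intervals(rr)
    n = x.size
    if n < 2:
        raise InsufficientDataError("rMSSD needs at least 2 intervals")
    d = np.diff(x)
    return float(np.sqrt(np.sum(d * d) / (n - 1)))


def compute_sdrr(rr) -> float:
    """Sample standard deviation of RR intervals (n-1 denominator), ms."""
    x = _as_intervals(rr)
    if x.size < 2:
        raise InsufficientDataError("SDRR needs at least 2 intervals")
    return float(np.std(x, ddof=1))


def compute_features(rr, prr_denominator: str = "n") -> HRVFeatureVector:
    """All 12 time-domain features of a strip's RR series.

    ``prr_denominator`` chooses the pRR20/pRR50 denominator: ``"n"`` (total
    interval count, the default) or ``"n-1"`` (successive-difference count,
    the conventional pNN50 form).
    """
    x = _as_intervals(rr)
    n = x.size
    if n < MIN_INTERVALS:
        raise InsufficientDataError(
            f"need at least {MIN_INTERVALS} intervals, got {n}"
        )
    if prr_denominator not in ("n", "n-1"):
        raise ParameterError("prr_denominator must be 'n' or 'n-1'")

    mean_rr = float(np.mean(x))
    median_rr = float(np.median(x))
    if mean_rr == 0 or median_rr == 0:
        raise ParameterError("degenerate RR series with zero mean/median")
    mad_rr = float(np.median(np.abs(x - median_rr)))
    sdrr = compute_sdrr(x)
    rmssd = compute_rmssd(x)

    d = np.abs(np.diff(x))
    rr20 = int(np.sum(d > 20.0))
    rr50 = int(np.sum(d > 50.0))
    denom = n if prr_denominator == "n" else n - 1

    return HRVFeatureVector(
        meanRR=mean_rr,
        medianRR=median_rr,
        madRR=mad_rr,
        mcvRR=mad_rr / median_rr,
        SDRR=sdrr,
        rMSSD=rmssd,
        CVRR=sdrr / mean_rr,
        CVSD=rmssd / mean_rr,
        RR20=float(rr20),
        pRR20=rr20 / denom,
        RR50=float(rr50),
        pRR50=rr50 / denom,
    )
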