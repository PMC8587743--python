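"""Labeled 30-s segment construction and the feature/label matrix.

Records are tiled into consecutive non-overlapping 30-s windows. A window
fully inside one rhythm interval takes that rhythm's label; windows touching
excluded (OTHER) rhythm regions or straddling an NSR/AF boundary are dropped.
Windows not already rhythm-labeled AF are re-examined against their beat
annotations: if every beat is in the N or S alphabet, at least one S beat is
present, and S beats make up strictly more than the saturation threshold
(default 50%), the window is treated as AF - the supraventricular-ectopy
saturation rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .errors import EmptyDatasetError, InsufficientDataError, ParameterError, StratificationError
from .hrv import MIN_INTERVALS, compute_features
from .io_formats import BeatAnnotations, RhythmIntervals, Signal
from .peaks import PeakDetectConfig, detect_peaks, peaks_to_rr

__all__ = [
    "SegmentRecord",
    "LabelRuleConfig",
    "segment_record",
    "build_feature_dataset",
    "stratified_split",
]

SEGMENT_S = 30.0

S_BEATS = frozenset("AaJSjen")
N_BEATS = frozenset("NLRB")


@dataclass
class SegmentRecord:
    """One labeled 30-s strip at the working rate (0 = NSR, 1 = AF)."""

    signal: Signal
    label: int
    source_id: str
    window_index: int = 0

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ParameterError("label must be 0 (NSR) or 1 (AF)")
        expected = int(round(SEGMENT_S * self.signal.fs))
        if self.signal.n != expected:
            raise ParameterError(
                f"segment must be exactly {expected} samples at {self.signal.fs} Hz, "
                f"got {self.signal.n}"
            )


@dataclass(frozen=True)
class LabelRuleConfig:
    """Window labeling rules (saturation threshold is a strict inequality)."""

    s_saturation_threshold: float = 0.5
    s_beat_alphabet: frozenset = S_BEATS
    n_beat_alphabet: frozenset = N_BEATS
    min_peaks_per_window: int = MIN_INTERVALS
    nsr_subsample_frac: float = 1.0   # record-level NSR thinning knob
    subsample_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.s_saturation_threshold <= 1:
            raise ParameterError("saturation threshold must be in (0, 1]")
        if self.s_beat_alphabet & self.n_beat_alphabet:
            raise ParameterError("beat alphabets must be disjoint")


def _window_rhythm(rhythms: RhythmIntervals, ws: float, we: float) -> str | None:
    """Rhythm fully covering [ws, we), 'MIXED' if straddling, None if uncovered."""
    touched = [
        r for (s, e, r) in rhythms.intervals if s < we and e > ws
    ]
    for s, e, r in rhythms.intervals:
        if s <= ws and e >= we:
            return r
    return "MIXED" if touched else None


def segment_record(
    sig: Signal,
    rhythms: RhythmIntervals,
    beats: BeatAnnotations,
    rules: LabelRuleConfig | None = None,
    source_id: str = "record",
) -> list[SegmentRecord]:
    """Tile a record into labeled 30-s segments per the rhythm + beat rules."""
    if rules is None:
        rules = LabelRuleConfig()
    win_n = int(round(SEGMENT_S * sig.fs))
    n_windows = sig.n // win_n
    out: list[SegmentRecord] = []
    for w in range(n_windows):
        ws = sig.t0_ms + 1000.0 * w * win_n / sig.fs
        we = ws + SEGMENT_S * 1000.0
        rhythm = _window_rhythm(rhythms, ws, we)
        if rhythm in ("OTHER", "MIXED"):
            continue  # excluded rhythm or boundary-straddling window
        label: int | None = 1 if rhythm == "AF" else (0 if rhythm == "NSR" else None)
        if label != 1:
            # saturation re-examination of non-AF windows
            in_win = (beats.times_ms >= ws) & (beats.times_ms < we)
            syms = [beats.labels[i] for i in np.flatnonzero(in_win)]
            if syms:
                known = rules.s_beat_alphabet | rules.n_beat_alphabet
                s_count = sum(1 for s in syms if s in rules.s_beat_alphabet)
                if (
                    all(s in known for s in syms)
                    and s_count > 0
                    and s_count / len(syms) > rules.s_saturation_threshold
                ):
                    label = 1
        if label is None:
            continue  # no rhythm label and saturation did not fire
        samples = sig.samples[w * win_n : (w + 1) * win_n]
        out.append(
            SegmentRecord(
                signal=Signal(samples, fs=sig.fs, modality=sig.modality, t0_ms=ws),
                label=label,
                source_id=source_id,
                window_index=w,
            )
        )
    return out


def build_feature_dataset(
    segments: list[SegmentRecord],
    detect_config: PeakDetectConfig | None = None,
    min_peaks_per_window: int = MIN_INTERVALS,
    prr_denominator: str = "n",
):
    """Per segment: detect peaks -> RR intervals -> 12 HRV features.

    Returns ``(X, y, kept_ids, dropped)`` with row-aligned feature matrix and
    labels; segments yielding fewer than ``min_peaks_per_window`` peaks are
    dropped and reported in ``dropped`` as ``(id, reason)`` pairs.
    """
    rows, labels, kept_ids, dropped = [], [], [], []
    for seg in segments:
        seg_key = f"{seg.source_id}:{seg.window_index}"
        try:
            pk = detect_peaks(seg.signal, detect_config)
        except ParameterError as exc:
            raise ParameterError(f"segment {seg_key}: {exc}") from exc
        if len(pk) < max(min_peaks_per_window, MIN_INTERVALS + 1):
            dropped.append((seg_key, f"only {len(pk)} peaks detected"))
            continue
        try:
            feats = compute_features(peaks_to_rr(pk), prr_denominator=prr_denominator)
        except InsufficientDataError as exc:
            dropped.append((seg_key, str(exc)))
            continue
        rows.append(feats.to_array())
        labels.append(seg.label)
        kept_ids.append(seg_key)
    if not rows:
        raise EmptyDatasetError("all segments were dropped during feature extraction")
    if dropped:
        warnings.warn(f"dropped {len(dropped)} segment(s) with too few beats", stacklevel=2)
    return np.vstack(rows), np.asarray(labels, dtype=int), kept_ids, dropped


def stratified_split(labels, train_frac: float = 0.8, seed: int = 0):
    """Stratified index split into (train+validation, test) partitions."""
    labels = np.asarray(labels)
    if not 0 < train_frac < 1:
        raise ParameterError("train_frac must be in (0, 1)")
    if len(np.unique(labels)) < 2:
        raise StratificationError("both classes must be present to stratify")
    idx = np.arange(labels.size)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_frac, stratify=labels, random_state=int(seed)
    )
    return np.sort(train_idx), np.sort(test_idx)
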