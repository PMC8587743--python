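import numpy as np
import pytest

from pulseaf.dataset import (
    SegmentRecord,
    build_feature_dataset,
    segment_record,
    stratified_split,
)
from pulseaf.errors import EmptyDatasetError, ParameterError, StratificationError
from pulseaf.io_formats import BeatAnnotations, RhythmIntervals, Signal
from pulseaf.preprocess import bandpass_filter
from pulseaf.synthetic import gen_corpus


def _flat_signal(duration_s, fs=50.0):
    return Signal(np.zeros(int(duration_s * fs)), fs=fs, modality="ecg")


def _beats(times_ms, labels):
    return BeatAnnotations(np.asarray(times_ms, dtype=float), labels)


class TestSegmentRecord:
    def test_single_nsr_rhythm_tiles_fully(self):
        sig = _flat_signal(35 * 60)  # 35 minutes
        rhythms = RhythmIntervals([(0.0, 35 * 60 * 1000.0, "NSR")])
        segs = segment_record(sig, rhythms, _beats([], []), source_id="r1")
        assert len(segs) == 70  # floor(2100 s / 30 s)
        assert all(s.label == 0 for s in segs)
        assert [s.window_index for s in segs] == list(range(70))

    def test_trailing_partial_window_discarded(self):
        sig = _flat_signal(75)  # 2.5 windows
        rhythms = RhythmIntervals([(0.0, 75000.0, "NSR")])
        assert len(segment_record(sig, rhythms, _beats([], []))) == 2

    def test_saturation_rule_over_half_s_beats(self):
        # 10 beats, 6 'A' -> 0.6 > 0.5 -> AF despite NSR rhythm label
        sig = _flat_signal(30)
        rhythms = RhythmIntervals([(0.0, 30000.0, "NSR")])
        times = np.linspace(1000, 29000, 10)
        labels = ["A"] * 6 + ["N"] * 4
        segs = segment_record(sig, rhythms, _beats(times, labels))
        assert len(segs) == 1 and segs[0].label == 1

    def test_saturation_rule_exactly_half_not_af(self):
        # 5/10 = 0.5 is not "over 50%": retains the NSR rhythm label
        sig = _flat_signal(30)
        rhythms = RhythmIntervals([(0.0, 30000.0, "NSR")])
        times = np.linspace(1000, 29000, 10)
        segs = segment_record(sig, rhythms, _beats(times, ["A"] * 5 + ["N"] * 5))
        assert len(segs) == 1 and segs[0].label == 0

    def test_zero_s_beats_ignored_by_saturation(self):
        # all-N window with no rhythm label is not labeled by saturation
        sig = _flat_signal(30)
        segs = segment_record(
            sig, RhythmIntervals([]), _beats(np.linspace(500, 29000, 8), ["N"] * 8)
        )
        assert segs == []

    def test_window_overlapping_other_rhythm_dropped(self):
        sig = _flat_signal(60)
        rhythms = RhythmIntervals([(0.0, 30000.0, "OTHER"), (30000.0, 60000.0, "AF")])
        segs = segment_record(sig, rhythms, _beats([], []))
        assert len(segs) == 1 and segs[0].label == 1 and segs[0].window_index == 1

    def test_boundary_straddling_window_dropped(self):
        sig = _flat_signal(90)
        rhythms = RhythmIntervals([(0.0, 45000.0, "NSR"), (45000.0, 90000.0, "AF")])
        segs = segment_record(sig, rhythms, _beats([], []))
        # window [30 s, 60 s) straddles the boundary and is dropped
        assert [s.window_index for s in segs] == [0, 2]
        assert [s.label for s in segs] == [0, 1]

    def test_labeling_is_deterministic(self):
        sig = _flat_signal(60)
        rhythms = RhythmIntervals([(0.0, 60000.0, "AF")])
        beats = _beats(np.linspace(500, 59000, 20), ["N"] * 20)
        a = segment_record(sig, rhythms, beats)
        b = segment_record(sig, rhythms, beats)
        assert [(s.label, s.window_index) for s in a] == [(s.label, s.window_index) for s in b]

    def test_segment_length_invariant(self):
        with pytest.raises(ParameterError):
            SegmentRecord(_flat_signal(29), label=0, source_id="x")


class TestBuildFeatureDataset:
    def test_clean_corpus_keeps_all_segments(self):
        segments, manifest = gen_corpus(10, 0, fs=50.0, modality="ecg", seed=5)
        for s in segments:
            s.signal = bandpass_filter(s.signal)
        X, y, kept, dropped = build_feature_dataset(segments)
        assert X.shape == (10, 12) and dropped == []
        assert (y == 0).all()

    def test_labels_follow_generator_manifest(self):
        segments, manifest = gen_corpus(6, 6, fs=50.0, modality="ecg", seed=9)
        for s in segments:
            s.signal = bandpass_filter(s.signal)
        X, y, kept, dropped = build_feature_dataset(segments)
        truth = {m["segment_id"]: m["label"] for m in manifest}
        for key, label in zip(kept, y):
            assert truth[key.split(":")[0]] == label

    def test_beatless_segment_dropped_with_log(self, rng):
        segments, _ = gen_corpus(3, 0, fs=50.0, modality="ecg", seed=2)
        for s in segments:
            s.signal = bandpass_filter(s.signal)
        flat = SegmentRecord(
            Signal(np.zeros(1500), fs=50.0, modality="ecg"), 0, "flat", 0
        )
        with pytest.warns(UserWarning, match="dropped"):
            X, y, kept, dropped = build_feature_dataset(segments + [flat])
        assert len(dropped) == 1 and dropped[0][0].startswith("flat")
        assert X.shape[0] == 3

    def test_all_dropped_raises(self):
        flat = SegmentRecord(Signal(np.zeros(1500), fs=50.0, modality="ecg"), 0, "f", 0)
        with pytest.raises(EmptyDatasetError):
            build_feature_dataset([flat])


class TestStratifiedSplit:
    def test_proportions_preserved(self):
        labels = np.array([0] * 60 + [1] * 40)
        train, test = stratified_split(labels, 0.8, seed=1)
        assert len(train) == 80 and len(test) == 20
        assert (labels[train] == 0).sum() == 48 and (labels[train] == 1).sum() == 32

    def test_deterministic_and_exhaustive(self):
        labels = np.array([0, 1] * 50)
        t1 = stratified_split(labels, 0.8, seed=42)
        t2 = stratified_split(labels, 0.8, seed=42)
        np.testing.assert_array_equal(t1[0], t2[0])
        combined = np.sort(np.concatenate(t1))
        np.testing.assert_array_equal(combined, np.arange(100))

    def test_single_class_rejected(self):
        with pytest.raises(StratificationError):
            stratified_split(np.zeros(10, dtype=int))
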