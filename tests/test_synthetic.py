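import json

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from pulseaf.errors import ParameterError
from pulseaf.hrv import compute_features
from pulseaf.peaks import RRSeries, detect_peaks, peaks_to_rr
from pulseaf.preprocess import bandpass_filter, resample_fft
from pulseaf.synthetic import (
    AFModel,
    NoiseModel,
    NSRModel,
    WaveformModel,
    gen_corpus,
    gen_rr_series,
    gen_waveform,
)


class TestRRGeneration:
    def test_nsr_moment_recovery(self):
        rr = gen_rr_series(NSRModel(), 10_000, seed=1)
        se = 90.0 / np.sqrt(10_000)
        assert abs(rr.intervals_ms.mean() - 926.0) <= 3 * se * np.sqrt(
            (1 + 0.7) / (1 - 0.7)  # AR(1) inflates the standard error of the mean
        )
        assert rr.intervals_ms.std(ddof=1) == pytest.approx(90.0, rel=0.1)

    def test_af_is_highly_irregular(self):
        rr = gen_rr_series(AFModel(), 10_000, seed=2)
        f = compute_features(rr.intervals_ms)
        assert f.rMSSD > 100.0
        assert f.pRR50 > 0.4

    def test_seed_reproducibility(self):
        a = gen_rr_series(NSRModel(), 100, seed=7)
        b = gen_rr_series(NSRModel(), 100, seed=7)
        np.testing.assert_array_equal(a.intervals_ms, b.intervals_ms)

    def test_floor_respected(self):
        rr = gen_rr_series(AFModel(sd_ms=400.0), 5000, seed=3)
        assert rr.intervals_ms.min() >= 300.0

    def test_too_few_beats_rejected(self):
        with pytest.raises(ParameterError):
            gen_rr_series(NSRModel(), 1, seed=0)


class TestWaveformRendering:
    def test_truth_peaks_at_cumulative_times(self):
        rr = RRSeries([800.0, 800.0])
        sig, truth = gen_waveform(rr, WaveformModel(), fs=50.0, modality="ecg")
        np.testing.assert_allclose(truth.times_ms, [0.0, 800.0, 1600.0])
        # signal local argmaxima sit within one sample of each truth index
        for idx in truth.indices[1:]:  # the t=0 peak is half rendered
            window = sig.samples[max(0, idx - 2) : idx + 3]
            assert abs(np.argmax(window) + max(0, idx - 2) - idx) <= 1

    def test_mild_noise_keeps_argmaxima(self):
        hits = total = 0
        for seed in range(100):
            rr = RRSeries([800.0, 800.0, 800.0])
            sig, truth = gen_waveform(
                rr, WaveformModel(noise=NoiseModel(snr_db=40.0)),
                fs=50.0, modality="ecg", seed=seed, t_first_ms=500.0,
            )
            for idx in truth.indices:
                lo = max(0, idx - 2)
                local = lo + np.argmax(sig.samples[lo : idx + 3])
                hits += int(abs(local - idx) <= 1)
                total += 1
        assert hits == total

    def test_ppg_double_pulse_morphology(self):
        rr = RRSeries([900.0] * 3)
        sig, truth = gen_waveform(rr, WaveformModel(), fs=100.0, modality="ppg",
                                  t_first_ms=300.0)
        # diastolic bump raises the signal ~250 ms after each systolic peak,
        # but below the systolic amplitude
        i_sys = truth.indices[1]
        i_dia = i_sys + 25  # 250 ms at 100 Hz
        assert sig.samples[i_dia] < sig.samples[i_sys]
        assert sig.samples[i_dia] > 0.2

    def test_powerline_removed_by_chain(self):
        # 50 Hz interference injected at 250 Hz native rate must be >= 30 dB
        # down after the ECG bandpass + resample chain
        rr = RRSeries(np.full(30, 800.0))
        clean, _ = gen_waveform(rr, WaveformModel(), fs=250.0, modality="ecg",
                                t_first_ms=500.0)
        noisy, _ = gen_waveform(
            rr, WaveformModel(noise=NoiseModel(powerline_amp=0.5, powerline_hz=50.0)),
            fs=250.0, modality="ecg", seed=0, t_first_ms=500.0,
        )
        powerline = noisy.samples - clean.samples
        # linear chain: its response to the interference alone is the
        # difference between the chained noisy and clean renders
        out_noisy = resample_fft(bandpass_filter(noisy), 50.0)
        out_clean = resample_fft(bandpass_filter(clean), 50.0)
        residual = out_noisy.samples - out_clean.samples
        p_in = np.mean(powerline**2)
        p_out = np.mean(residual**2)
        assert 10 * np.log10(p_in / max(p_out, 1e-300)) >= 30.0


class TestCorpus:
    def test_counts_and_manifest_complete(self):
        segments, manifest = gen_corpus(5, 7, fs=50.0, modality="ppg", seed=7)
        assert len(segments) == 12 and len(manifest) == 12
        assert sum(m["label"] for m in manifest) == 7
        for m in manifest:
            assert {"segment_id", "label", "seed", "true_peak_times_ms",
                    "true_features"} <= set(m)
            assert len(m["true_peak_times_ms"]) >= 5

    def test_manifests_byte_identical_across_runs(self):
        _, m1 = gen_corpus(4, 4, fs=50.0, modality="ecg", seed=11)
        _, m2 = gen_corpus(4, 4, fs=50.0, modality="ecg", seed=11)
        assert json.dumps(m1, sort_keys=True) == json.dumps(m2, sort_keys=True)

    def test_detected_features_close_to_truth(self):
        segments, manifest = gen_corpus(20, 20, fs=50.0, modality="ecg", seed=13)
        rel_errs = {"rMSSD": [], "SDRR": []}
        for seg, meta in zip(segments, manifest):
            feats = compute_features(
                peaks_to_rr(detect_peaks(bandpass_filter(seg.signal)))
            )
            for name in rel_errs:
                truth = meta["true_features"][name]
                if truth > 0:
                    rel_errs[name].append(abs(getattr(feats, name) - truth) / truth)
        for name, errs in rel_errs.items():
            assert np.median(errs) <= 0.05, f"{name} median rel err {np.median(errs):.3f}"

    def test_af_separation_premise(self):
        # the classifier's premise: AF strips have systematically higher
        # rMSSD, pRR50 and CVRR than NSR strips
        segments, manifest = gen_corpus(100, 100, fs=50.0, modality="ecg", seed=17)
        nsr = [m["true_features"] for m in manifest if m["label"] == 0]
        af = [m["true_features"] for m in manifest if m["label"] == 1]
        for key in ("rMSSD", "pRR50", "CVRR"):
            a = [m[key] for m in af]
            n = [m[key] for m in nsr]
            assert np.median(a) > np.median(n)
            assert mannwhitneyu(a, n, alternative="greater").pvalue < 1e-10
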