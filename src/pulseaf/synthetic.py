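"""Seeded generation of synthetic rhythm strips with ground truth.

RR-interval models
------------------
Normal sinus rhythm is an AR(1) Gaussian process around a normative mean of
926 ms with stationary sd 90 ms (the short-term reference range for healthy
adults) and lag-1 correlation 0.7, so successive differences stay small and
rMSSD lands in the normative 19-75 ms band. Atrial fibrillation has no
published RR distribution to copy; the AF model here is synthetic scaffolding
built to express the defining physiology - highly irregular, essentially
uncorrelated intervals - as an i.i.d. mixture of a wide Gaussian (mean 700 ms,
sd 180 ms) with occasional uniform(350, 1400) ms jumps. Both are floored to
keep intervals physiologic.

Waveforms
---------
Beats are rendered as templates placed at cumulative RR times: a narrow
Gaussian bump (sigma 20 ms) with small P/T bumps for ECG, and a
systolic+diastolic double Gaussian (sigmas 60/90 ms, diastolic delayed 250 ms
at 0.4 amplitude) for PPG. Optional noise: white (by SNR), baseline-wander
sine, powerline sine, and short motion bursts. Ground-truth peak times equal
the template placement times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .io_formats import Signal
from .hrv import compute_features, FEATURE_NAMES
from .peaks import PeakList, RRSeries

__all__ = [
    "NSRModel",
    "AFModel",
    "WaveformModel",
    "NoiseModel",
    "gen_rr_series",
    "gen_waveform",
    "gen_corpus",
    "DEFAULT_NSR",
    "DEFAULT_AF",
    "SHIFTED_PPG_NSR",
    "SHIFTED_PPG_AF",
]


@dataclass(frozen=True)
class NSRModel:
    """AR(1) RR model for normal sinus rhythm (ms)."""

    mean_ms: float = 926.0
    sd_ms: float = 90.0
    rho: float = 0.7
    floor_ms: float = 400.0

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ParameterError("rho must be in [0, 1)")
        if self.sd_ms < 0 or self.mean_ms <= self.floor_ms:
            raise ParameterError("invalid NSR RR parameters")


@dataclass(frozen=True)
class AFModel:
    """i.i.d. heavy-mixture RR model for atrial fibrillation (ms)."""

    mean_ms: float = 700.0
    sd_ms: float = 180.0
    jump_weight: float = 0.2
    jump_low_ms: float = 350.0
    jump_high_ms: float = 1400.0
    floor_ms: float = 300.0

    def __post_init__(self) -> None:
        if not 0 <= self.jump_weight <= 1:
            raise ParameterError("jump_weight must be in [0, 1]")
        if self.jump_low_ms >= self.jump_high_ms:
            raise ParameterError("jump range inverted")


DEFAULT_NSR = NSRModel()
DEFAULT_AF = AFModel()

# Distribution-shifted models standing in for a wrist-PPG cohort: pulse-rate
# variability under motion artifact inflates normal-rhythm variability and
# shifts rates, while AF looks less extreme than on the ECG training data.
SHIFTED_PPG_NSR = NSRModel(mean_ms=820.0, sd_ms=150.0, rho=0.25, floor_ms=400.0)
SHIFTED_PPG_AF = AFModel(mean_ms=780.0, sd_ms=150.0, jump_weight=0.10)


@dataclass(frozen=True)
class NoiseModel:
    """Additive disturbances applied to a rendered waveform."""

    snr_db: float | None = None           # white noise level, None = off
    baseline_amp: float = 0.0             # fraction of peak amplitude
    baseline_hz: float = 0.3
    powerline_amp: float = 0.0            # fraction of peak amplitude
    powerline_hz: float = 50.0
    motion_rate_hz: float = 0.0           # burst events per second
    motion_amp: float = 0.0


@dataclass(frozen=True)
class WaveformModel:
    """Beat templates for ECG-like and PPG-like rendering."""

    qrs_sigma_ms: float = 20.0
    qrs_amp: float = 1.0
    p_amp: float = 0.12
    p_sigma_ms: float = 30.0
    p_offset_ms: float = -180.0
    t_amp: float = 0.25
    t_sigma_ms: float = 70.0
    t_offset_ms: float = 220.0
    sys_sigma_ms: float = 60.0
    sys_amp: float = 1.0
    dia_sigma_ms: float = 90.0
    dia_amp: float = 0.4
    dia_offset_ms: float = 250.0
    noise: NoiseModel = field(default_factory=NoiseModel)


def gen_rr_series(model, n_beats: int, seed) -> RRSeries:
    """Draw ``n_beats`` RR intervals from an :class:`NSRModel` or :class:`AFModel`."""
    if n_beats < 2:
        raise ParameterError("n_beats must be >= 2")
    rng = np.random.default_rng(seed)
    if isinstance(model, NSRModel):
        innov_sd = model.sd_ms * math.sqrt(1.0 - model.rho**2)
        x = np.empty(n_beats)
        x[0] = model.mean_ms + model.sd_ms * rng.standard_normal()
        eps = innov_sd * rng.standard_normal(n_beats - 1)
        for i in range(1, n_beats):
            x[i] = model.mean_ms + model.rho * (x[i - 1] - model.mean_ms) + eps[i - 1]
    elif isinstance(model, AFModel):
        base = model.mean_ms + model.sd_ms * rng.standard_normal(n_beats)
        jumps = rng.uniform(model.jump_low_ms, model.jump_high_ms, n_beats)
        is_jump = rng.random(n_beats) < model.jump_weight
        x = np.where(is_jump, jumps, base)
    else:
        raise ParameterError(f"unknown RR model type {type(model).__name__}")
    return RRSeries(np.maximum(x, model.floor_ms))


def _add_bumps(out, t_ms, centers_ms, amp, sigma_ms):
    # evaluate each Gaussian bump only on a local window: cheap and exact to 5 sigma
    dt = t_ms[1] - t_ms[0] if t_ms.size > 1 else 1.0
    half = int(math.ceil(5 * sigma_ms / dt))
    for c in centers_ms:
        i0 = max(0, int((c - t_ms[0]) / dt) - half)
        i1 = min(t_ms.size, int((c - t_ms[0]) / dt) + half + 1)
        if i1 <= i0:
            continue
        d = t_ms[i0:i1] - c
        out[i0:i1] += amp * np.exp(-0.5 * (d / sigma_ms) ** 2)


def gen_waveform(
    rr: RRSeries,
    model: WaveformModel,
    fs: float,
    modality: str,
    seed=None,
    t_first_ms: float = 0.0,
    duration_ms: float | None = None,
) -> tuple[Signal, PeakList]:
    """Render an RR series as a waveform plus its ground-truth peak list.

    Beats fall at ``t_first_ms + cumsum([0] + rr)``; the returned peak list
    holds exactly those placement times (restricted to the rendered span).
    """
    if fs < 50:
        raise ParameterError("rendering requires fs >= 50 Hz")
    if rr.n < 1:
        raise ParameterError("empty RR series")
    beat_times = t_first_ms + np.concatenate([[0.0], np.cumsum(rr.intervals_ms)])
    if duration_ms is None:
        duration_ms = beat_times[-1] + float(np.mean(rr.intervals_ms))
    n = int(round(duration_ms * fs / 1000.0))
    t_ms = 1000.0 * np.arange(n) / fs
    out = np.zeros(n)

    if modality == "ecg":
        _add_bumps(out, t_ms, beat_times, model.qrs_amp, model.qrs_sigma_ms)
        _add_bumps(out, t_ms, beat_times + model.p_offset_ms, model.p_amp, model.p_sigma_ms)
        _add_bumps(out, t_ms, beat_times + model.t_offset_ms, model.t_amp, model.t_sigma_ms)
        peak_amp = model.qrs_amp
    elif modality == "ppg":
        _add_bumps(out, t_ms, beat_times, model.sys_amp, model.sys_sigma_ms)
        _add_bumps(out, t_ms, beat_times + model.dia_offset_ms, model.dia_amp, model.dia_sigma_ms)
        peak_amp = model.sys_amp
    else:
        raise ParameterError(f"unknown modality {modality!r}")

    noise = model.noise
    rng = np.random.default_rng(seed)
    if noise.snr_db is not None:
        sig_power = float(np.mean(out**2))
        noise_sd = math.sqrt(sig_power / 10 ** (noise.snr_db / 10.0))
        out = out + noise_sd * rng.standard_normal(n)
    if noise.baseline_amp:
        phase = rng.uniform(0, 2 * math.pi)
        out = out + noise.baseline_amp * peak_amp * np.sin(
            2 * math.pi * noise.baseline_hz * t_ms / 1000.0 + phase
        )
    if noise.powerline_amp:
        phase = rng.uniform(0, 2 * math.pi)
        out = out + noise.powerline_amp * peak_amp * np.sin(
            2 * math.pi * noise.powerline_hz * t_ms / 1000.0 + phase
        )
    if noise.motion_rate_hz and noise.motion_amp:
        n_bursts = rng.poisson(noise.motion_rate_hz * duration_ms / 1000.0)
        for _ in range(n_bursts):
            c = rng.uniform(0, duration_ms)
            env = np.exp(-0.5 * ((t_ms - c) / 500.0) ** 2)
            out = out + noise.motion_amp * peak_amp * env * rng.standard_normal(n)

    in_span = beat_times < t_ms[-1] + 1000.0 / fs
    truth_times = beat_times[in_span]
    truth_idx = np.clip(np.round(truth_times * fs / 1000.0).astype(int), 0, n - 1)
    sig = Signal(out, fs=fs, modality=modality)
    truth = PeakList(
        indices=truth_idx, times_ms=truth_times, amplitudes=out[truth_idx]
    )
    return sig, truth


def _segment_seed(seed: int, index: int) -> int:
    # deterministic per-segment seed derivation, kept below 2**31
    return int((int(seed) * 1_000_003 + 7919 * index + 1) % (2**31 - 1))


def gen_corpus(
    n_nsr: int,
    n_af: int,
    nsr_model: NSRModel = DEFAULT_NSR,
    af_model: AFModel = DEFAULT_AF,
    waveform: WaveformModel | None = None,
    fs: float = 50.0,
    modality: str = "ecg",
    seed: int = 0,
    segment_s: float = 30.0,
):
    """Generate a labeled corpus of exact 30-s segments plus a truth manifest.

    Returns ``(segments, manifest)`` where each manifest entry records the
    class, the per-segment seed, the true peak times, and the HRV features of
    the true RR series inside the segment.
    """
    from .dataset import SegmentRecord  # local import avoids a cycle

    if n_nsr < 0 or n_af < 0 or n_nsr + n_af == 0:
        raise ParameterError("need at least one segment")
    if waveform is None:
        waveform = WaveformModel()
    seg_n = int(round(segment_s * fs))
    segments, manifest = [], []
    specs = [("nsr", 0, nsr_model)] * n_nsr + [("af", 1, af_model)] * n_af
    for i, (name, label, rr_model) in enumerate(specs):
        seg_seed = _segment_seed(seed, i)
        # enough beats to cover the window whatever the draw; floor bounds it
        n_beats = int(math.ceil(segment_s * 1000.0 / rr_model.floor_ms)) + 4
        rr = gen_rr_series(rr_model, n_beats, seg_seed)
        sig, truth = gen_waveform(
            rr, waveform, fs=fs, modality=modality, seed=seg_seed,
            t_first_ms=300.0, duration_ms=segment_s * 1000.0,
        )
        samples = sig.samples[:seg_n]
        if samples.size < seg_n:  # pragma: no cover - rounding guard
            samples = np.pad(samples, (0, seg_n - samples.size))
        seg_sig = Signal(samples, fs=fs, modality=modality)
        keep = truth.times_ms < segment_s * 1000.0
        truth_times = truth.times_ms[keep]
        true_rr = np.diff(truth_times)
        feats = compute_features(true_rr)
        seg_id = f"{name}_{i:04d}"
        segments.append(
            SegmentRecord(signal=seg_sig, label=label, source_id=seg_id, window_index=0)
        )
        manifest.append(
            {
                "segment_id": seg_id,
                "label": label,
                "class": name,
                "seed": seg_seed,
                "fs": fs,
                "modality": modality,
                "source_id": seg_id,
                "window_index": 0,
                "true_peak_times_ms": [round(float(t), 6) for t in truth_times],
                "true_features": {
                    k: round(float(v), 9)
                    for k, v in zip(FEATURE_NAMES, feats.to_array())
                },
            }
        )
    return segments, manifest
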