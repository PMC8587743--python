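"""Reading and writing the on-disk formats the pipeline touches.

Covers a minimal dialect of the PhysioBank WFDB family (header + signal data
in formats 16 and 212, and the binary beat/rhythm annotation stream), plain
CSV feature tables, and the package's own segment bundles (CSV + JSON sidecar).

Conventions used throughout the package: sample indices are 0-based, times are
in milliseconds, and all intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

__all__ = [
    "Signal",
    "BeatAnnotations",
    "RhythmIntervals",
    "read_wfdb_record",
    "write_wfdb_record",
    "read_wfdb_annotations",
    "write_wfdb_annotations",
    "write_feature_table",
    "read_feature_table",
    "write_segment_bundle",
    "read_segment_bundle",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class Signal:
    """A uniformly sampled single-channel waveform.

    Parameters
    ----------
    samples : ndarray
        Sensor values (arbitrary physical scale).
    fs : float
        Sampling rate in Hz, > 0.
    modality : str
        ``"ecg"`` or ``"ppg"``.
    t0_ms : float
        Time of sample 0 in milliseconds (default 0). Sample ``i`` occurs at
        ``t0_ms + 1000 * i / fs``.
    """

    samples: np.ndarray
    fs: float
    modality: str = "ecg"
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ParameterError("signal must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("signal contains non-finite samples")
        if not self.fs > 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        self.modality = str(self.modality).lower()
        if self.modality not in ("ecg", "ppg"):
            raise ParameterError(f"modality must be 'ecg' or 'ppg', got {self.modality!r}")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + 1000.0 * np.arange(self.n) / self.fs


@dataclass
class BeatAnnotations:
    """Per-beat annotation times (ms) and WFDB beat symbols."""

    times_ms: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.labels = list(self.labels)
        if len(self.times_ms) != len(self.labels):
            raise ParameterError("times and labels must have equal length")
        if len(self.times_ms) > 1 and not np.all(np.diff(self.times_ms) > 0):
            raise ParameterError("annotation times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class RhythmIntervals:
    """Non-overlapping half-open rhythm intervals ``(start_ms, end_ms, rhythm)``.

    ``rhythm`` is one of ``"NSR"``, ``"AF"``, ``"OTHER"``.
    """

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end, rhythm in self.intervals:
            if not start < end:
                raise ParameterError(f"empty or inverted interval [{start}, {end})")
            if start < prev_end:
                raise ParameterError("rhythm intervals overlap")
            if rhythm not in ("NSR", "AF", "OTHER"):
                raise ParameterError(f"unknown rhythm {rhythm!r}")
            prev_end = end

    def __len__(self) -> int:
        return len(self.intervals)

    def rhythm_at(self, t_ms: float) -> str | None:
        for start, end, rhythm in self.intervals:
            if start <= t_ms < end:
                return rhythm
        return None


# --------------------------------------------------------------------------
# WFDB records (header + signal data)
# --------------------------------------------------------------------------

def _parse_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"empty WFDB header: {hea_path}")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed WFDB record line: {lines[0]!r}")
    name, n_sig = head[0], int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    sig_specs = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise FormatError(f"malformed WFDB signal line: {ln!r}")
        fname = tok[0]
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = 200.0, 0
        if len(tok) >= 3:
            g = tok[2].split("/")[0]
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
            gain = float(g) if float(g) != 0 else 200.0
        adc_zero = int(tok[4]) if len(tok) >= 5 else 0
        if len(tok) < 3 or "(" not in tok[2]:
            baseline = adc_zero
        sig_specs.append({"file": fname, "fmt": fmt, "gain": gain, "baseline": baseline})
    return name, n_sig, fs, n_samples, sig_specs


def _read_dat(dat_path: Path, fmt: int, n_sig: int) -> np.ndarray:
    raw = dat_path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        data = data[: (len(data) // n_sig) * n_sig]
        return data.reshape(-1, n_sig)
    if fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (len(b) // 3) * 3].reshape(-1, 3).astype(np.int32)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s0[s0 > 2047] -= 4096
        s1[s1 > 2047] -= 4096
        data = np.empty(2 * len(b), dtype=np.int32)
        data[0::2], data[1::2] = s0, s1
        data = data[: (len(data) // n_sig) * n_sig]
        return data.reshape(-1, n_sig)
    raise FormatError(f"unsupported WFDB signal format {fmt}")


def read_wfdb_record(path: str | Path, channel: int = 0, modality: str = "ecg") -> Signal:
    """Read one channel of a WFDB record as a :class:`Signal`.

    ``path`` is the record path without extension (or the ``.hea`` file).
    Samples are converted to physical units via ``(adc - baseline) / gain``.
    The modality is supplied by the caller; WFDB does not encode it.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    name, n_sig, fs, n_samples, sig_specs = _parse_header(hea)
    if not 0 <= channel < n_sig:
        raise IndexError(f"channel {channel} out of range for {n_sig}-channel record")
    spec = sig_specs[channel]
    dat = hea.parent / spec["file"]
    if not dat.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat}")
    data = _read_dat(dat, spec["fmt"], n_sig)
    if n_samples:
        data = data[:n_samples]
    physical = (data[:, channel].astype(float) - spec["baseline"]) / spec["gain"]
    return Signal(physical, fs=fs, modality=modality)


def write_wfdb_record(
    path: str | Path,
    channels: Sequence[np.ndarray] | np.ndarray,
    fs: float,
    gain: float = 200.0,
    baseline: int = 0,
) -> None:
    """Write channels as a WFDB record (format 16, one interleaved .dat file).

    Values are quantized to ``round(x * gain) + baseline`` 16-bit integers;
    samples that are exact multiples of ``1/gain`` round-trip bit-identically.
    """
    path = Path(path)
    arr = np.atleast_2d(np.asarray(channels, dtype=float))
    if arr.shape[0] > arr.shape[1]:  # accept (n, ch) or (ch, n)
        arr = arr.T
    n_sig, n = arr.shape
    adc = np.round(arr * gain).astype(np.int64) + baseline
    if adc.min() < -32768 or adc.max() > 32767:
        raise ParameterError("samples exceed 16-bit ADC range at this gain")
    dat_name = path.stem + ".dat"
    with open(path.with_suffix(".hea"), "w") as fh:
        fh.write(f"{path.stem} {n_sig} {fs:g} {n}\n")
        for _ in range(n_sig):
            fh.write(f"{dat_name} 16 {gain:g}({baseline}) 16 {baseline} 0 0 0\n")
    interleaved = adc.T.astype("<i2").tobytes()
    (path.parent / dat_name).write_bytes(interleaved)


# --------------------------------------------------------------------------
# WFDB annotations (MIT binary format)
# --------------------------------------------------------------------------

# WFDB annotation code table (code -> mnemonic symbol)
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63

#: beat symbols considered actual beats (rhythm '+' markers are separate)
BEAT_SYMBOLS = frozenset("NLRBAaJSjenVFE/Qf!r")

#: default mapping from rhythm aux strings to the package's rhythm classes
DEFAULT_AF_AUX = frozenset({"(AFIB"})
DEFAULT_NSR_AUX = frozenset({"(N"})


def _raw_read_annotations(atr_path: Path):
    """Decode the MIT annotation stream into (sample, code, aux) tuples."""
    raw = atr_path.read_bytes()
    out: list[tuple[int, int, str | None]] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(raw) or (i < len(raw) and len(raw) - i == 1):
        if i + 2 > len(raw):
            break
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:
            break  # EOF
        if code == _SKIP:
            if i + 4 > len(raw):
                raise FormatError("truncated SKIP in annotation stream")
            hi = raw[i] | (raw[i + 1] << 8)
            lo = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            pending_skip = struct.unpack("<i", struct.pack("<I", (hi << 16) | lo))[0]
            continue
        if code in (_NUM, _SUB, _CHN):
            continue  # field modifiers, ignored
        if code == _AUX:
            n_aux = interval
            aux = raw[i : i + n_aux].rstrip(b"\x00").decode("latin-1")
            i += n_aux + (n_aux & 1)  # null pad to even
            if out:
                out[-1] = (out[-1][0], out[-1][1], aux)
            continue
        t += interval + pending_skip
        pending_skip = 0
        out.append((t, code, None))
    return out


def _raw_write_annotations(atr_path: Path, entries) -> None:
    """Encode (sample, code, aux) tuples as an MIT annotation stream."""
    buf = bytearray()
    prev = 0
    for sample, code, aux in entries:
        delta = sample - prev
        prev = sample
        if delta > 1023 or delta < 0:
            buf += struct.pack("<H", _SKIP << 10)
            packed = struct.pack("<i", delta)
            lo, hi = struct.unpack("<HH", packed)
            buf += struct.pack("<HH", hi, lo)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        if aux:
            aux_b = aux.encode("latin-1")
            buf += struct.pack("<H", (_AUX << 10) | len(aux_b))
            buf += aux_b
            if len(aux_b) & 1:
                buf += b"\x00"
    buf += struct.pack("<H", 0)  # EOF
    atr_path.write_bytes(bytes(buf))


def read_wfdb_annotations(
    path: str | Path,
    fs: float | None = None,
    end_ms: float | None = None,
    af_aux: frozenset[str] | set[str] = DEFAULT_AF_AUX,
) -> tuple[BeatAnnotations, RhythmIntervals]:
    """Read a WFDB annotation file into beats + half-open rhythm intervals.

    Rhythm change markers ('+' annotations with aux strings) are converted to
    intervals mapped as ``"(N"`` -> NSR, any member of ``af_aux`` -> AF,
    anything else -> OTHER. ``fs`` defaults to the value in the sibling
    ``.hea`` header; ``end_ms`` (closing time of the last interval) defaults
    to the last annotation time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    if fs is None:
        hea = path.with_suffix(".hea")
        if not hea.exists():
            raise ParameterError("fs not given and no sibling .hea header found")
        fs = _parse_header(hea)[2]
    try:
        entries = _raw_read_annotations(path)
    except (struct.error, IndexError) as exc:  # pragma: no cover - defensive
        raise FormatError(f"unparseable annotation stream: {path}") from exc

    beat_times, beat_labels = [], []
    changes: list[tuple[float, str]] = []
    for sample, code, aux in entries:
        t_ms = 1000.0 * sample / fs
        sym = _CODE_TO_SYMBOL.get(code)
        if sym == "+":
            label = aux or ""
            if label in af_aux:
                changes.append((t_ms, "AF"))
            elif label in DEFAULT_NSR_AUX:
                changes.append((t_ms, "NSR"))
            else:
                changes.append((t_ms, "OTHER"))
        elif sym is not None and sym in BEAT_SYMBOLS:
            beat_times.append(t_ms)
            beat_labels.append(sym)

    beats = BeatAnnotations(np.array(beat_times, dtype=float), beat_labels)
    intervals: list[tuple[float, float, str]] = []
    if changes:
        if end_ms is None:
            all_times = [t for t, _, _ in entries]
            end_ms = 1000.0 * max(all_times) / fs if all_times else changes[-1][0]
        for (t0, rhythm), (t1, _) in zip(changes, changes[1:] + [(end_ms, "")]):
            if t1 > t0:
                intervals.append((t0, t1, rhythm))
    return beats, RhythmIntervals(intervals)


def write_wfdb_annotations(
    path: str | Path,
    beats: BeatAnnotations,
    rhythms: RhythmIntervals | None = None,
    fs: float = 250.0,
) -> None:
    """Write beats (and optional rhythm change markers) as a WFDB .atr file."""
    entries: list[tuple[int, int, str | None]] = []
    for t_ms, sym in zip(beats.times_ms, beats.labels):
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ParameterError(f"no WFDB code for beat symbol {sym!r}")
        entries.append((int(round(t_ms * fs / 1000.0)), code, None))
    if rhythms is not None:
        aux_map = {"NSR": "(N", "AF": "(AFIB", "OTHER": "(OTHER"}
        for start, _end, rhythm in rhythms.intervals:
            entries.append(
                (int(round(start * fs / 1000.0)), _SYMBOL_TO_CODE["+"], aux_map[rhythm])
            )
    entries.sort(key=lambda e: e[0])
    _raw_write_annotations(Path(path), entries)


# --------------------------------------------------------------------------
# Feature tables and segment bundles
# --------------------------------------------------------------------------

# fixed feature ordering shared with the hrv module (kept here to avoid a cycle)
FEATURE_NAMES = (
    "meanRR", "medianRR", "madRR", "mcvRR", "SDRR", "rMSSD",
    "CVRR", "CVSD", "RR20", "pRR20", "RR50", "pRR50",
)


def write_feature_table(
    rows: Sequence[tuple[np.ndarray, int, str]], path: str | Path
) -> None:
    """Write ``(feature_vector, label, source_id)`` rows as a CSV table."""
    records = []
    for vec, label, source_id in rows:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(FEATURE_NAMES),):
            raise ParameterError(
                f"feature vector must have {len(FEATURE_NAMES)} entries, got {vec.shape}"
            )
        rec = dict(zip(FEATURE_NAMES, vec))
        rec["label"] = int(label)
        rec["source_id"] = str(source_id)
        records.append(rec)
    df = pd.DataFrame(records, columns=list(FEATURE_NAMES) + ["label", "source_id"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> list[tuple[np.ndarray, int, str]]:
    """Read a feature CSV back; columns are matched by header name."""
    df = pd.read_csv(path)
    missing = [c for c in list(FEATURE_NAMES) + ["label", "source_id"] if c not in df.columns]
    if missing:
        raise FormatError(f"feature table missing columns: {missing}")
    rows = []
    for _, r in df.iterrows():
        vec = np.array([float(r[name]) for name in FEATURE_NAMES])
        rows.append((vec, int(r["label"]), str(r["source_id"])))
    return rows


def write_segment_bundle(directory: str | Path, segments, manifest: list[dict]) -> None:
    """Write segments as per-segment CSVs plus a ``manifest.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for seg, meta in zip(segments, manifest):
        seg_id = meta["segment_id"]
        np.savetxt(directory / f"{seg_id}.csv", seg.signal.samples, fmt="%.9g")
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def read_segment_bundle(directory: str | Path):
    """Read a segment bundle directory back into (segments, manifest)."""
    from .dataset import SegmentRecord  # local import avoids a cycle

    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    segments = []
    for meta in manifest:
        samples = np.loadtxt(directory / f"{meta['segment_id']}.csv")
        sig = Signal(samples, fs=meta["fs"], modality=meta["modality"])
        segments.append(
            SegmentRecord(
                signal=sig,
                label=int(meta["label"]),
                source_id=str(meta["source_id"]),
                window_index=int(meta.get("window_index", 0)),
            )
        )
    return segments, manifest
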