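#!/usr/bin/env python
"""Optional: run the full ECG training protocol on locally supplied MIT-BIH data.

This script is *not* part of the package's automated checks. The published
full-database results depend on PhysioNet downloads (MIT-BIH NSR, AF and
Arrhythmia databases) plus an unspecified arbitrary selection of normal-rhythm
records, and the wrist-PPG test set is access-restricted, so they are not
reproducible from this repository alone. Given a local directory of WFDB
records with beat/rhythm annotations, this runs the same pipeline:
30-s segmentation with rhythm + S-beat-saturation labeling, bandpass + 50 Hz
resampling, two-moving-average peak detection, 12 HRV features, and the
stratified 5-fold CNN protocol.

Usage:
    python scripts/reproduce_ecg_protocol.py --data-dir /path/to/wfdb \
        [--nsr-record-frac 0.15] [--seed 0] [--out metrics.json]

``--data-dir`` must contain WFDB header/data/annotation triples
(record.hea / record.dat / record.atr).
"""

from __future__ import annotations

import argparse
import json
import sys
from pathlib import Path

import numpy as np

from pulseaf.dataset import build_feature_dataset, segment_record
from pulseaf.io_formats import read_wfdb_annotations, read_wfdb_record
from pulseaf.model_eval import TrainConfig, train_cv
from pulseaf.preprocess import WORKING_FS, bandpass_filter, resample_fft


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, required=True)
    ap.add_argument("--channel", type=int, default=0)
    ap.add_argument("--nsr-record-frac", type=float, default=0.15,
                    help="Fraction of pure-NSR records to keep (seeded).")
    ap.add_argument("--epochs", type=int, default=50)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=None)
    args = ap.parse_args()

    records = sorted(args.data_dir.glob("*.hea")) if args.data_dir.is_dir() else []
    if not records:
        print(
            f"error: no WFDB data found under {args.data_dir}; supply a directory "
            "of locally downloaded MIT-BIH records (.hea/.dat/.atr)",
            file=sys.stderr,
        )
        return 2

    rng = np.random.default_rng(args.seed)
    segments = []
    for hea in records:
        sig = read_wfdb_record(hea, channel=args.channel, modality="ecg")
        atr = hea.with_suffix(".atr")
        if not atr.exists():
            print(f"skipping {hea.stem}: no annotation file", file=sys.stderr)
            continue
        beats, rhythms = read_wfdb_annotations(atr, fs=sig.fs, end_ms=sig.duration_ms)
        rhythm_set = {r for _, _, r in rhythms.intervals}
        if rhythm_set == {"NSR"} and rng.random() > args.nsr_record_frac:
            continue  # record-level NSR thinning, seeded
        sig = resample_fft(bandpass_filter(sig), WORKING_FS)
        segments.extend(segment_record(sig, rhythms, beats, source_id=hea.stem))

    if not segments:
        print("error: no labeled 30-s segments could be built", file=sys.stderr)
        return 3

    X, y, kept, dropped = build_feature_dataset(segments)
    print(f"{len(y)} segments ({int(y.sum())} AF), {len(dropped)} dropped")
    res = train_cv(X, y, TrainConfig(epochs=args.epochs, seed=args.seed))
    report = {
        "cv_mean": {k: round(v, 2) for k, v in res.cv_mean.items()},
        "cv_sd": {k: round(v, 2) for k, v in res.cv_sd.items()},
        "holdout": res.holdout_report.to_dict(),
        "n_segments": len(y),
        "n_af": int(y.sum()),
    }
    text = json.dumps(report, indent=1)
    print(text)
    if args.out:
        args.out.write_text(text)
    return 0


if __name__ == "__main__":
    sys.exit(main())
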