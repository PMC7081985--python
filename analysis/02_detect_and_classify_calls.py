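#!/usr/bin/env python
"""Detect and classify vocalizations from the session audio.

Runs the envelope detector, measures de-noised-FFT peak frequencies,
applies the 50-kHz class rule and the LHF split, flags temporally
isolated calls, and scores everything against the generator's ground
truth.  Writes results/call_classification.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, ensure_dirs

from vocolock.synth import read_wav
from vocolock.vocal import (
    characterize_calls,
    detect_calls,
    read_event_csv,
    select_isolated,
)


def main() -> None:
    ensure_dirs()
    audio, fs = read_wav(SCRATCH / "audio.wav")
    truth = read_event_csv(RESULTS / "events.csv")
    detected = detect_calls(audio, fs)
    detected = characterize_calls(audio, fs, detected)
    detected = select_isolated(detected, recording_bounds=(0.0, audio.size / fs))

    rows = []
    for ev in detected:
        match = min(truth, key=lambda t: abs(t.onset_s - ev.onset_s))
        hit = abs(match.onset_s - ev.onset_s) < 2e-3
        rows.append({
            "onset_s": ev.onset_s, "duration_ms": ev.duration_ms,
            "peak_freq_khz": ev.peak_freq_khz, "class": ev.class_label,
            "subclass": ev.subclass, "isolated": ev.isolated,
            "true_class": match.class_label if hit else None,
            "class_correct": hit and ev.class_label == match.class_label,
        })
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "call_classification.csv", index=False)
    n_true = len(truth)
    acc = df["class_correct"].mean() * 100
    med = df.groupby("class")["peak_freq_khz"].median()
    print(f"detected {len(df)}/{n_true} calls; class recovery {acc:.1f}%")
    for cls, pk in med.items():
        print(f"  median peak frequency, {cls}: {pk:.1f} kHz")
    print(f"isolated: {int(df['isolated'].sum())}")


if __name__ == "__main__":
    main()
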