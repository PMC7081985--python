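#!/usr/bin/env python
"""Condition the raw traces into analysis-ready epochs and spike trains.

Band-pass 1-90 Hz, remove line noise, downsample 20 kHz -> 1 kHz, z-score
(FAF across channels, CN per channel), epoch +/-500 ms around isolated
call onsets; detect multi-unit spikes at 5 MADs and build 3-ms PSTHs.
Writes scratch/epochs.h5 (+ contaminated-trial epochs) and
scratch/{spikes.csv,psth.csv}.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, ensure_dirs

from vocolock import conditioning
from vocolock.conditioning import NeuralRecording
from vocolock.vocal import read_event_csv


def main() -> None:
    ensure_dirs()
    raw = NeuralRecording.from_hdf5(SCRATCH / "recording.h5")
    events = read_event_csv(RESULTS / "events.csv")

    rec = conditioning.bandpass_lfp(raw)
    rec = conditioning.remove_line_noise(rec)
    rec = conditioning.downsample(rec, 1000.0)
    rec = conditioning.zscore_by_structure(rec)
    iso = [e for e in events if e.isolated]
    cont = [e for e in events if e.contaminated_post]
    epochs = conditioning.extract_epochs(rec, iso)
    epochs.to_hdf5(SCRATCH / "epochs.h5")
    conditioning.extract_epochs(rec, cont).to_hdf5(SCRATCH / "epochs_contaminated.h5")

    spikes = conditioning.detect_spikes(raw)
    conditioning.write_spike_csv(spikes, SCRATCH / "spikes.csv")
    onsets = np.array([e.onset_s for e in iso])
    rows = []
    for tr in spikes:
        centers, rate = conditioning.psth(tr.times_s, onsets)
        for c, r in zip(centers, rate):
            rows.append({"channel": tr.channel, "t_s": c, "spikes_per_trial": r})
    pd.DataFrame(rows).to_csv(SCRATCH / "psth.csv", index=False)

    counts = [tr.times_s.size for tr in spikes]
    print(f"epochs: {epochs.n_trials} isolated trials "
          f"({(epochs.labels['class'] == 'echolocation').sum()} echolocation, "
          f"{(epochs.labels['class'] == 'communication').sum()} communication), "
          f"{len(cont)} contaminated-post")
    print(f"spikes per channel: {counts}")


if __name__ == "__main__":
    main()
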