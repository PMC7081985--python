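#!/usr/bin/env python
"""Generate the study session: audio + wideband neural traces + spikes.

Writes the event table and ground truth to results/, and the bulky
regenerable artifacts (WAV audio, raw-trace HDF5) to scratch/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, SESSION, ensure_dirs

from vocolock.conditioning import write_spike_csv
from vocolock.synth import generate_session, write_wav
from vocolock.vocal import write_event_csv


def main() -> None:
    ensure_dirs()
    session = generate_session(SESSION, with_audio=True)
    write_event_csv(session.events, RESULTS / "events.csv")
    session.ground_truth.to_json(RESULTS / "ground_truth.json")
    write_wav(SCRATCH / "audio.wav", session.audio, session.fs_audio_hz)
    session.recording.to_hdf5(SCRATCH / "recording.h5")
    write_spike_csv(session.spike_trains, SCRATCH / "spikes_groundtruth.csv")
    n_iso = sum(e.isolated for e in session.events)
    n_cont = sum(e.contaminated_post for e in session.events)
    print(
        f"session: {session.recording.duration_s:.0f} s, "
        f"{session.recording.n_channels} channels, {len(session.events)} calls "
        f"({n_iso} isolated, {n_cont} contaminated-post); "
        f"audio {session.audio.size / session.fs_audio_hz:.0f} s @ "
        f"{session.fs_audio_hz / 1e3:.0f} kHz"
    )


if __name__ == "__main__":
    main()
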