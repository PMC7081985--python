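"""Detection, characterization and classification of bat vocalizations.

Two call classes are distinguished by their spectral content: echolocation
pulses are short (<2 ms), downward frequency-modulated, and peak above
50 kHz, while communication calls carry most energy below 50 kHz.
Communication calls splitting additional energy into the high frequencies
form the LHF subclass (low-and-high-frequency), the rest the LF subclass.

Peak frequency is measured on the *de-noised* FFT: the magnitude spectrum of
a duration-matched noise snippet is subtracted from the call's magnitude
spectrum and the difference floored at zero before taking the argmax.

Only temporally isolated calls — at least 500 ms without any other
vocalization before onset and after offset — enter the neural analyses.
Calls with a clean pre-window but another vocalization inside the
post-window are kept separately (``contaminated_post``) as a control set
for decoder generalization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "CallEvent",
    "CallSpectrum",
    "detect_calls",
    "call_spectrogram",
    "peak_frequency",
    "denoised_spectrum",
    "classify_call",
    "subclassify_communication",
    "select_isolated",
    "characterize_calls",
    "events_to_frame",
    "frame_to_events",
    "write_event_csv",
    "read_event_csv",
]

#: Class boundary in kHz: peak above this -> echolocation, at or below ->
#: communication.
CLASS_BOUNDARY_KHZ = 50.0


@dataclass
class CallEvent:
    """One detected vocalization on the audio timeline (seconds, 0-based)."""

    onset_s: float
    offset_s: float
    peak_freq_khz: float = np.nan
    class_label: str | None = None  # 'echolocation' | 'communication'
    subclass: str | None = None  # 'LF' | 'LHF' | None
    isolated: bool = False
    contaminated_post: bool = False

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"offset ({self.offset_s}) must exceed onset ({self.onset_s})"
            )

    @property
    def duration_ms(self) -> float:
        return (self.offset_s - self.onset_s) * 1e3


@dataclass
class CallSpectrum:
    """Magnitude spectrum of one call; optionally noise-floor subtracted."""

    freq_khz: np.ndarray
    power: np.ndarray
    denoised: bool = False

    def __post_init__(self) -> None:
        self.freq_khz = np.asarray(self.freq_khz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freq_khz.shape != self.power.shape:
            raise ValueError("freq and power grids must match")
        if self.denoised and np.any(self.power < 0):
            raise ValueError("de-noised power must be floored at zero")


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def detect_calls(
    audio: np.ndarray,
    fs: float,
    threshold_mad: float = 5.0,
    min_gap_ms: float = 1.0,
    smooth_ms: float = 0.1,
    threshold: float | None = None,
    min_dur_ms: float = 0.2,
) -> list[CallEvent]:
    """Detect supra-threshold energy segments in an audio trace.

    The envelope is the rectified signal smoothed with a ``smooth_ms`` moving
    average.  The detection threshold is ``median + threshold_mad * MAD/0.6745``
    of the envelope unless an absolute ``threshold`` is given.  Maximal
    supra-threshold segments separated by gaps shorter than ``min_gap_ms``
    are merged; merged segments shorter than ``min_dur_ms`` (single-sample
    noise excursions) are discarded.  Returns onset/offset-only events
    sorted by onset; silent audio yields an empty list.
    """
    audio = np.asarray(audio, dtype=float)
    if not np.all(np.isfinite(audio)):
        raise ValueError("audio contains non-finite samples")
    if audio.size == 0:
        return []
    win = max(1, int(round(smooth_ms * 1e-3 * fs)))
    env = np.convolve(np.abs(audio), np.ones(win) / win, mode="same")
    if threshold is None:
        threshold = np.median(env) + threshold_mad * _mad(env) / 0.6745
    above = env > threshold
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)  # exclusive
    # merge across short gaps
    min_gap = int(round(min_gap_ms * 1e-3 * fs))
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, stops):
        if merged and s - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    min_dur = min_dur_ms * 1e-3 * fs
    return [
        CallEvent(onset_s=s / fs, offset_s=e / fs)
        for s, e in merged
        if e - s >= min_dur
    ]


def call_spectrogram(
    waveform: np.ndarray,
    fs: float,
    frame_ms: float = 0.8,
    step_ms: float = 0.05,
    nfft: int = 2048,
):
    """Hamming-window spectrogram of a call at audio resolution.

    Frame width 0.8 ms, frame shift 0.05 ms, 2,048-point FFT (frames are
    zero-padded).  Returns a :class:`~vocolock.spectral.TimeFrequencyMap`
    with linear power values; a waveform shorter than one frame yields a
    single-frame map.
    """
    from .spectral import TimeFrequencyMap

    waveform = np.asarray(waveform, dtype=float)
    nperseg = max(2, int(round(frame_ms * 1e-3 * fs)))
    hop = max(1, int(round(step_ms * 1e-3 * fs)))
    if waveform.size < nperseg:
        waveform = np.pad(waveform, (0, nperseg - waveform.size))
    nfft = max(nfft, nperseg)
    freqs, times, sxx = signal.spectrogram(
        waveform,
        fs=fs,
        window=signal.get_window("hamming", nperseg),
        nperseg=nperseg,
        noverlap=nperseg - hop,
        nfft=nfft,
        mode="psd",
        detrend=False,
    )
    return TimeFrequencyMap(
        time=times,
        freq=freqs,
        values=sxx,
        kind="power",
        params={"frame_ms": frame_ms, "step_ms": step_ms, "nfft": nfft, "fs": fs},
    )


def denoised_spectrum(
    call_waveform: np.ndarray, noise_waveform: np.ndarray, fs: float
) -> CallSpectrum:
    """De-noised magnitude spectrum: max(|FFT(call)| - |FFT(noise)|, 0).

    Call and noise snippets must be duration-matched.
    """
    call = np.asarray(call_waveform, dtype=float)
    noise = np.asarray(noise_waveform, dtype=float)
    if call.shape != noise.shape:
        raise ValueError("call and noise snippets must have equal length")
    if call.size == 0:
        raise ValueError("empty snippet")
    diff = np.maximum(np.abs(np.fft.rfft(call)) - np.abs(np.fft.rfft(noise)), 0.0)
    freqs_khz = np.fft.rfftfreq(call.size, d=1.0 / fs) / 1e3
    return CallSpectrum(freq_khz=freqs_khz, power=diff, denoised=True)


def peak_frequency(
    call_waveform: np.ndarray, noise_waveform: np.ndarray, fs: float
) -> float:
    """Peak frequency (kHz) of the de-noised FFT; NaN when undefined.

    The peak is the argmax of the floored spectral difference; exact ties are
    broken toward the lower frequency.  An all-zero difference (e.g. call
    identical to noise) has no defined peak and returns NaN.
    """
    spec = denoised_spectrum(call_waveform, noise_waveform, fs)
    if not np.any(spec.power > 0):
        return float("nan")
    return float(spec.freq_khz[int(np.argmax(spec.power))])


def classify_call(peak_freq_khz: float, boundary_khz: float = CLASS_BOUNDARY_KHZ) -> str:
    """Peak above 50 kHz -> 'echolocation'; at or below -> 'communication'."""
    if not np.isfinite(peak_freq_khz):
        raise ValueError("peak frequency undefined; cannot classify")
    return "echolocation" if peak_freq_khz > boundary_khz else "communication"


def subclassify_communication(
    spectrum: CallSpectrum, split_khz: float = CLASS_BOUNDARY_KHZ, ratio: float = 0.5
) -> str:
    """LF/LHF rule for communication calls.

    With H the power maximum above ``split_khz`` and L the maximum at or
    below it, the call is LHF when ``H >= ratio * L`` (boundary inclusive),
    else LF.  An empty high band is LF.
    """
    hi = spectrum.freq_khz > split_khz
    lo = ~hi
    if not hi.any() or not np.any(spectrum.power[hi] > 0):
        return "LF"
    h = float(np.max(spectrum.power[hi]))
    l = float(np.max(spectrum.power[lo])) if lo.any() else 0.0
    return "LHF" if h >= ratio * l else "LF"


def select_isolated(
    events: list[CallEvent],
    pre_s: float = 0.5,
    post_s: float = 0.5,
    recording_bounds: tuple[float, float] | None = None,
) -> list[CallEvent]:
    """Flag events with >= ``pre_s``/``post_s`` of silence around them.

    ``isolated`` requires no other event overlapping the pre- or post-window
    and, when ``recording_bounds`` is given, the full margins inside the
    recording.  ``contaminated_post`` marks events whose pre-window is clean
    but whose post-window contains another vocalization (decoder control
    set).  Order-independent and idempotent; returns new events.
    """
    out = []
    for ev in events:
        pre_clean = True
        post_clean = True
        for other in events:
            if other is ev:
                continue
            if other.offset_s > ev.onset_s - pre_s and other.onset_s < ev.onset_s:
                pre_clean = False
            if other.onset_s < ev.offset_s + post_s and other.offset_s > ev.offset_s:
                post_clean = False
        if recording_bounds is not None:
            t0, t1 = recording_bounds
            if ev.onset_s - pre_s < t0:
                pre_clean = False
            if ev.offset_s + post_s > t1:
                post_clean = False
        out.append(
            dataclasses.replace(
                ev,
                isolated=pre_clean and post_clean,
                contaminated_post=pre_clean and not post_clean,
            )
        )
    return out


def characterize_calls(
    audio: np.ndarray,
    fs: float,
    events: list[CallEvent],
    noise_guard_ms: float = 1.0,
    boundary_khz: float = CLASS_BOUNDARY_KHZ,
) -> list[CallEvent]:
    """Measure peak frequency and assign class/subclass for each event.

    The noise-floor snippet is taken immediately preceding the call onset
    (duration-matched, separated by ``noise_guard_ms``).  Events whose noise
    snippet would fall outside the recording use a trailing snippet instead.
    """
    audio = np.asarray(audio, dtype=float)
    out = []
    for ev in events:
        i0 = int(round(ev.onset_s * fs))
        i1 = max(i0 + 2, int(round(ev.offset_s * fs)))
        i1 = min(i1, audio.size)
        n = i1 - i0
        guard = int(round(noise_guard_ms * 1e-3 * fs))
        n0 = i0 - guard - n
        noise = audio[n0 : n0 + n] if n0 >= 0 else audio[i1 + guard : i1 + guard + n]
        if noise.size != n:
            noise = np.zeros(n)
        pk = peak_frequency(audio[i0:i1], noise, fs)
        label = classify_call(pk, boundary_khz) if np.isfinite(pk) else None
        sub = None
        if label == "communication":
            sub = subclassify_communication(
                denoised_spectrum(audio[i0:i1], noise, fs), split_khz=boundary_khz
            )
        out.append(
            dataclasses.replace(ev, peak_freq_khz=pk, class_label=label, subclass=sub)
        )
    return out


# ---------------------------------------------------------------------------
# event-table I/O (CSV schema: onset_s, offset_s, class, subclass, isolated,
# contaminated_post, peak_freq_khz)

def events_to_frame(events: list[CallEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [e.onset_s for e in events],
            "offset_s": [e.offset_s for e in events],
            "class": [e.class_label for e in events],
            "subclass": [e.subclass for e in events],
            "isolated": [e.isolated for e in events],
            "contaminated_post": [e.contaminated_post for e in events],
            "peak_freq_khz": [e.peak_freq_khz for e in events],
        }
    )


def frame_to_events(df: pd.DataFrame) -> list[CallEvent]:
    events = []
    for _, row in df.iterrows():
        cls = row.get("class")
        sub = row.get("subclass")
        events.append(
            CallEvent(
                onset_s=float(row["onset_s"]),
                offset_s=float(row["offset_s"]),
                peak_freq_khz=float(row.get("peak_freq_khz", np.nan)),
                class_label=None if pd.isna(cls) else str(cls),
                subclass=None if pd.isna(sub) else str(sub),
                isolated=bool(row.get("isolated", False)),
                contaminated_post=bool(row.get("contaminated_post", False)),
            )
        )
    return events


def write_event_csv(events: list[CallEvent], path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_event_csv(path) -> list[CallEvent]:
    return frame_to_events(pd.read_csv(path))
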