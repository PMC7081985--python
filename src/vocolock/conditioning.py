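"""Raw wideband traces -> analysis-ready LFP epochs, spike trains, PSTHs.

The LFP chain: band-pass 1-90 Hz (order-2 Butterworth, zero-phase),
sliding-window line-noise regression, downsample 20 kHz -> 1 kHz, z-score
(across channels for the frontal probe so amplitude relationships across
depths survive; per channel for the striatal tetrode), epoch +/-500 ms
around call onsets.

The spike chain: band-pass 300-3,000 Hz, threshold at 5 median absolute
deviations (Gaussian-consistent, MAD/0.6745), negative-going crossings with
spike time at the trough and a 1-ms refractory lockout.  This is multi-unit
threshold activity, not sorted single units.

All filtering is forward-backward (zero-phase): downstream phase analyses
cannot tolerate causal filter lag.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "NeuralRecording",
    "EpochSet",
    "SpikeTrain",
    "bandpass_lfp",
    "remove_line_noise",
    "downsample",
    "zscore_recording",
    "zscore_by_structure",
    "extract_epochs",
    "detect_spikes",
    "psth",
    "best_frequency",
    "write_spike_csv",
    "read_spike_csv",
]


@dataclass
class NeuralRecording:
    """Multichannel extracellular recording with per-channel metadata.

    ``channel_meta`` has one row per channel with columns ``structure``
    ('FAF' or 'CN') and ``depth_um``; depths are unique within a structure.
    """

    traces: np.ndarray  # channels x samples
    fs_hz: float
    channel_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_meta) != self.traces.shape[0]:
            raise ValueError("channel_meta rows must match trace channels")
        for struct, grp in self.channel_meta.groupby("structure"):
            if grp["depth_um"].duplicated().any():
                raise ValueError(f"duplicate depths within structure {struct!r}")

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def duration_s(self) -> float:
        return self.traces.shape[1] / self.fs_hz

    def channels(self, structure: str) -> np.ndarray:
        """Indices of channels in one structure, ordered by depth."""
        meta = self.channel_meta
        idx = np.flatnonzero((meta["structure"] == structure).to_numpy())
        return idx[np.argsort(meta["depth_um"].to_numpy()[idx], kind="stable")]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("raw", data=self.traces, track_times=False)
            f.attrs["fs_hz"] = self.fs_hz
            meta = f.create_group("meta")
            meta.create_dataset("structure", data=np.array(self.channel_meta["structure"], dtype="S8"),
                track_times=False,
            )
            meta.create_dataset("depth_um", data=self.channel_meta["depth_um"].to_numpy(float), track_times=False
            )

    @classmethod
    def from_hdf5(cls, path) -> "NeuralRecording":
        with h5py.File(path, "r") as f:
            traces = f["raw"][()]
            fs = float(f.attrs["fs_hz"])
            meta = pd.DataFrame(
                {
                    "structure": [s.decode() for s in f["meta/structure"][()]],
                    "depth_um": f["meta/depth_um"][()],
                }
            )
        return cls(traces=traces, fs_hz=fs, channel_meta=meta)


@dataclass
class EpochSet:
    """Event-aligned LFP epochs: trials x channels x time, call onset at t=0."""

    data: np.ndarray
    time: np.ndarray  # seconds relative to onset
    fs_hz: float
    labels: pd.DataFrame  # per trial: class, subclass, onset_s, ...
    channel_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[2] != self.time.size:
            raise ValueError("time axis length mismatch")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal n trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def condition(self, class_label: str, subclass: str | None = None) -> "EpochSet":
        """Sub-select trials of one call class (optionally subclass)."""
        mask = (self.labels["class"] == class_label).to_numpy()
        if subclass is not None:
            mask &= (self.labels["subclass"] == subclass).to_numpy()
        return EpochSet(
            data=self.data[mask],
            time=self.time,
            fs_hz=self.fs_hz,
            labels=self.labels.loc[mask].reset_index(drop=True),
            channel_meta=self.channel_meta,
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("epochs", data=self.data, track_times=False)
            f.create_dataset("time", data=self.time, track_times=False)
            f.attrs["fs_hz"] = self.fs_hz
            lab = f.create_group("labels")
            for col in self.labels.columns:
                vals = self.labels[col].to_numpy()
                if vals.dtype == object:
                    vals = np.array(["" if v is None else str(v) for v in vals], dtype="S16")
                lab.create_dataset(col, data=vals, track_times=False)

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            data = f["epochs"][()]
            time = f["time"][()]
            fs = float(f.attrs["fs_hz"])
            cols = {}
            for col in f["labels"]:
                vals = f["labels"][col][()]
                if vals.dtype.kind == "S":
                    vals = np.array([v.decode() or None for v in vals], dtype=object)
                cols[col] = vals
        return cls(data=data, time=time, fs_hz=fs, labels=pd.DataFrame(cols))


@dataclass
class SpikeTrain:
    """Threshold-crossing spike times (s) for one channel."""

    times_s: np.ndarray
    channel: int
    threshold_mad: float = np.nan

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.size > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("spike times must be strictly increasing")


def _check_finite(rec: NeuralRecording) -> None:
    if not np.all(np.isfinite(rec.traces)):
        raise ValueError("recording contains non-finite samples")


def _zero_phase_bandpass(
    x: np.ndarray, fs: float, low: float, high: float, order: int = 2
) -> np.ndarray:
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def bandpass_lfp(
    rec: NeuralRecording, low_hz: float = 1.0, high_hz: float = 90.0, order: int = 2
) -> NeuralRecording:
    """Zero-phase order-2 Butterworth band-pass, 1-90 Hz by default."""
    if rec.fs_hz < 2 * high_hz:
        raise ValueError("sampling rate below twice the upper band edge")
    _check_finite(rec)
    return dataclasses.replace(
        rec, traces=_zero_phase_bandpass(rec.traces, rec.fs_hz, low_hz, high_hz, order)
    )


def remove_line_noise(
    rec: NeuralRecording,
    line_hz: float = 50.0,
    win_s: float = 1.0,
    step_s: float = 0.5,
    n_harmonics: int = 2,
) -> NeuralRecording:
    """Subtract mains interference by sliding-window sinusoid regression.

    Per window, sine/cosine pairs at ``line_hz`` and its first
    ``n_harmonics - 1`` harmonics are least-squares fitted and subtracted;
    windows are combined by Hann-weighted overlap-add.  Tracking the line
    component in short windows follows it through slow amplitude/phase
    drifts.  Clean input passes through essentially unchanged.
    """
    if line_hz >= rec.fs_hz / 2:
        raise ValueError("line frequency above Nyquist")
    if win_s < 2.0 / line_hz:
        raise ValueError("window must span at least two line cycles")
    _check_finite(rec)
    fs = rec.fs_hz
    n = rec.traces.shape[1]
    win = min(int(round(win_s * fs)), n)
    step = max(1, int(round(step_s * fs)))
    t = np.arange(win) / fs
    cols = []
    for h in range(1, n_harmonics + 1):
        w = 2 * np.pi * line_hz * h
        cols += [np.cos(w * t), np.sin(w * t)]
    design = np.column_stack(cols)  # win x 2H
    pinv = np.linalg.pinv(design)
    taper = signal.windows.hann(win, sym=False) + 1e-12
    out = np.zeros_like(rec.traces)
    norm = np.zeros(n)
    starts = list(range(0, max(n - win, 0) + 1, step))
    if starts[-1] != n - win:
        starts.append(n - win)
    for s in starts:
        seg = rec.traces[:, s : s + win]
        fitted = (pinv @ seg.T).T @ design.T  # line-component estimate
        out[:, s : s + win] += (seg - fitted) * taper
        norm[s : s + win] += taper
    return dataclasses.replace(rec, traces=out / norm)


def downsample(rec: NeuralRecording, target_fs: float = 1000.0) -> NeuralRecording:
    """Anti-alias filter and decimate to ``target_fs`` (integer factor only)."""
    factor = rec.fs_hz / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"target_fs {target_fs} is not an integer divisor of fs {rec.fs_hz}"
        )
    factor = int(round(factor))
    if factor == 1:
        return rec
    _check_finite(rec)
    traces = signal.resample_poly(rec.traces, up=1, down=factor, axis=-1)
    return dataclasses.replace(rec, traces=traces, fs_hz=target_fs)


def zscore_recording(
    rec: NeuralRecording, mode: str = "per_channel", channels: np.ndarray | None = None
) -> NeuralRecording:
    """Z-score traces over the whole recording.

    ``per_channel``: each channel gets its own mean/std.  ``across_channels``:
    a single mean/std from the pooled selected channels is applied to each,
    preserving amplitude relationships across channels.
    """
    _check_finite(rec)
    traces = rec.traces.copy()
    idx = np.arange(rec.n_channels) if channels is None else np.asarray(channels)
    sub = traces[idx]
    stds = sub.std(axis=1)
    if np.any(stds == 0):
        bad = idx[np.flatnonzero(stds == 0)[0]]
        raise ValueError(f"zero-variance channel {bad}; cannot z-score")
    if mode == "per_channel":
        traces[idx] = (sub - sub.mean(axis=1, keepdims=True)) / stds[:, None]
    elif mode == "across_channels":
        mu, sd = sub.mean(), sub.std()
        traces[idx] = (sub - mu) / sd
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return dataclasses.replace(rec, traces=traces)


def zscore_by_structure(rec: NeuralRecording) -> NeuralRecording:
    """Across-channels z-score for FAF, per-channel for CN."""
    faf = rec.channels("FAF")
    cn = rec.channels("CN")
    out = rec
    if faf.size:
        out = zscore_recording(out, mode="across_channels", channels=faf)
    if cn.size:
        out = zscore_recording(out, mode="per_channel", channels=cn)
    return out


def extract_epochs(
    rec: NeuralRecording,
    events,
    window: tuple[float, float] = (-0.5, 0.5),
) -> EpochSet:
    """Cut trials x channels x time epochs around call onsets.

    ``events`` is a list of CallEvents (or a DataFrame with ``onset_s``).
    The t=0 sample is the sample nearest each onset.  Events whose window
    leaves the recording are skipped with a warning.
    """
    if hasattr(events, "itertuples"):
        from .vocal import frame_to_events

        events = frame_to_events(events)
    fs = rec.fs_hz
    pre = int(round(-window[0] * fs))
    post = int(round(window[1] * fs))
    time = np.arange(-pre, post + 1) / fs
    n = rec.traces.shape[1]
    rows, data = [], []
    for ev in events:
        center = int(round(ev.onset_s * fs))
        if center - pre < 0 or center + post >= n:
            warnings.warn(
                f"event at {ev.onset_s:.3f}s outside recording margins; skipped",
                stacklevel=2,
            )
            continue
        data.append(rec.traces[:, center - pre : center + post + 1])
        rows.append(
            {
                "onset_s": ev.onset_s,
                "class": ev.class_label,
                "subclass": ev.subclass,
                "isolated": ev.isolated,
                "contaminated_post": ev.contaminated_post,
            }
        )
    data = (
        np.stack(data)
        if data
        else np.empty((0, rec.n_channels, time.size))
    )
    return EpochSet(
        data=data,
        time=time,
        fs_hz=fs,
        labels=pd.DataFrame(rows, columns=["onset_s", "class", "subclass", "isolated", "contaminated_post"]),
        channel_meta=rec.channel_meta,
    )


def detect_spikes(
    rec: NeuralRecording,
    threshold_mad: float = 5.0,
    band: tuple[float, float] = (300.0, 3000.0),
    lockout_ms: float = 1.0,
) -> list[SpikeTrain]:
    """Threshold multi-unit spike detection on the high-pass band.

    Traces are band-passed 300-3,000 Hz (zero-phase order 2); the threshold
    is ``threshold_mad`` Gaussian-consistent MADs (MAD/0.6745) below zero;
    each negative-going crossing contributes one spike at its trough, with a
    ``lockout_ms`` refractory lockout.  Scale-invariant by construction.
    """
    if rec.fs_hz < 2 * band[1]:
        raise ValueError("sampling rate too low for the spike band")
    _check_finite(rec)
    filt = _zero_phase_bandpass(rec.traces, rec.fs_hz, *band)
    lockout = int(round(lockout_ms * 1e-3 * rec.fs_hz))
    trains = []
    for ch in range(rec.n_channels):
        x = filt[ch]
        mad = np.median(np.abs(x - np.median(x))) / 0.6745
        thr = -threshold_mad * mad
        below = x < thr
        padded = np.concatenate(([False], below, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        stops = np.flatnonzero(d == -1)
        troughs = [s + int(np.argmin(x[s:e])) for s, e in zip(starts, stops)]
        kept: list[int] = []
        for t in troughs:
            if not kept or t - kept[-1] >= lockout:
                kept.append(t)
        trains.append(
            SpikeTrain(
                times_s=np.asarray(kept, dtype=float) / rec.fs_hz,
                channel=ch,
                threshold_mad=threshold_mad,
            )
        )
    return trains


def psth(
    spike_times_s: np.ndarray,
    event_onsets_s: np.ndarray,
    bin_ms: float = 3.0,
    window: tuple[float, float] = (-0.5, 0.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Peristimulus time histogram: spikes per trial per bin.

    Returns ``(bin_centers_s, rate)`` where ``rate[i]`` is the total spike
    count in half-open bin ``[left, right)`` divided by the number of trials.
    """
    onsets = np.asarray(event_onsets_s, dtype=float)
    if onsets.size == 0:
        raise ValueError("psth requires at least one trial")
    spikes = np.asarray(spike_times_s, dtype=float)
    width = bin_ms * 1e-3
    n_bins = int(round((window[1] - window[0]) / width))
    edges = window[0] + width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for onset in onsets:
        rel = spikes - onset
        rel = rel[(rel >= edges[0]) & (rel < edges[-1])]
        counts += np.histogram(rel, bins=edges)[0]
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, counts / onsets.size


def best_frequency(
    epochs_by_freq: dict[float, np.ndarray],
    fs_hz: float,
    time: np.ndarray,
    post_window: tuple[float, float] = (0.0, 0.2),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pure-tone tuning: best frequency per channel via Hilbert energy.

    For each stimulus frequency (kHz) the trial-averaged LFP is Hilbert
    transformed and the instantaneous energy (|analytic signal|) summed over
    the post-onset window.  The frequency maximizing the energy is the
    channel's best frequency; ties go to the lower frequency.

    Returns ``(freqs_khz, best_freq_khz_per_channel, tuning_curve)`` with
    ``tuning_curve`` of shape (n_freqs, n_channels).
    """
    freqs = np.array(sorted(epochs_by_freq))
    if freqs.size == 1:
        warnings.warn("single-frequency grid; best frequency is trivial", stacklevel=2)
    time = np.asarray(time)
    sel = (time >= post_window[0]) & (time <= post_window[1])
    curves = []
    for f in freqs:
        epochs = np.asarray(epochs_by_freq[f], dtype=float)  # trials x ch x time
        mean_lfp = epochs.mean(axis=0)
        energy = np.abs(signal.hilbert(mean_lfp, axis=-1))[:, sel].sum(axis=-1)
        curves.append(energy)
    tuning = np.stack(curves)  # n_freq x n_ch
    best = freqs[np.argmax(tuning, axis=0)]
    return freqs, best, tuning


def write_spike_csv(trains: list[SpikeTrain], path) -> None:
    rows = [
        {"channel": tr.channel, "time_s": t, "threshold_mad": tr.threshold_mad}
        for tr in trains
        for t in tr.times_s
    ]
    pd.DataFrame(rows, columns=["channel", "time_s", "threshold_mad"]).to_csv(
        path, index=False
    )


def read_spike_csv(path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    trains = []
    for ch, grp in df.groupby("channel"):
        thr = grp["threshold_mad"].iloc[0] if "threshold_mad" in grp else np.nan
        trains.append(
            SpikeTrain(
                times_s=np.sort(grp["time_s"].to_numpy(float)),
                channel=int(ch),
                threshold_mad=float(thr),
            )
        )
    return trains
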