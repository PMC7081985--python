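"""Synthetic audio + neural sessions with the statistical structure the
analyses assume, plus a ground-truth record for parameter-recovery tests.

What the generator emulates
---------------------------
* Vocalizations: short (<2 ms) downward-FM echolocation pulses peaking near
  72 kHz and longer low-frequency communication calls peaking near 14 kHz,
  with an LHF communication variant carrying extra energy above 50 kHz.
  Calls are cosine-tapered tones/sweeps embedded in a low-level noise
  track sampled at 250 kHz.
* LFP background: 1/f^alpha noise (default alpha = 1) made by spectral
  shaping of white noise — exactly seedable.
* Call-locked structure: Gaussian-windowed band-limited bursts injected
  around call onsets per a burst table (class-, region- and
  depth-dependent), a shared low-frequency component between FAF and CN
  with a class-dependent time window and inter-areal lag (coherence
  table), and a deterministic post-call evoked deflection in deep FAF
  channels.  Burst phases are drawn uniformly per trial, so randomization
  averaging keeps only power (not waveform) differences, as the
  locked-spectral method assumes; coherence components share their phase
  across regions up to the stated lag.
* Spiking: an inhomogeneous Poisson process (thinning) whose intensity
  follows a von Mises modulation exp(kappa*cos(phase - preferred)) of a
  configurable LFP band phase, elevated post-call by an evoked gain.
  Spike waveforms (negative-dominant, ~0.5 ms) are added to the wideband
  trace so threshold detection can be exercised against ground truth.

Identical configs (including seed) produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0

from .conditioning import EpochSet, NeuralRecording, SpikeTrain
from .vocal import CallEvent, select_isolated

__all__ = [
    "CallClassSpec",
    "BurstSpec",
    "CoherenceSpec",
    "SpikeCouplingSpec",
    "SessionConfig",
    "GroundTruth",
    "SessionResult",
    "ECHOLOCATION_SPEC",
    "COMMUNICATION_LF_SPEC",
    "COMMUNICATION_LHF_SPEC",
    "pink_noise",
    "generate_call_audio",
    "generate_phase_locked_spikes",
    "generate_session",
    "generate_condition_epochs",
    "write_wav",
    "read_wav",
]


# ---------------------------------------------------------------------------
# call templates

@dataclass(frozen=True)
class CallClassSpec:
    """Spectro-temporal template of one call class."""

    class_label: str  # 'echolocation' | 'communication'
    subclass: str = "none"  # 'LF' | 'LHF' | 'none'
    duration_ms: float = 1.0
    peak_freq_khz: float = 72.0
    fm_sweep: str = "down"  # 'down' | 'none'
    hf_component_gain: float = 0.0  # LHF only
    hf_peak_khz: float = 60.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if self.peak_freq_khz <= 0:
            raise ValueError("peak frequency must be positive")
        if self.hf_component_gain < 0:
            raise ValueError("hf_component_gain must be >= 0")
        if self.class_label == "echolocation" and self.peak_freq_khz <= 50:
            raise ValueError("echolocation template must peak above 50 kHz")
        if self.subclass == "LF" and (
            self.peak_freq_khz >= 50 or self.hf_component_gain != 0
        ):
            raise ValueError("LF template: peak < 50 kHz and no HF component")
        if self.subclass == "LHF" and self.hf_component_gain <= 0:
            raise ValueError("LHF template requires hf_component_gain > 0")


ECHOLOCATION_SPEC = CallClassSpec(
    "echolocation", "none", duration_ms=1.0, peak_freq_khz=72.0, fm_sweep="down"
)
COMMUNICATION_LF_SPEC = CallClassSpec(
    "communication", "LF", duration_ms=5.0, peak_freq_khz=14.0, fm_sweep="none"
)
COMMUNICATION_LHF_SPEC = CallClassSpec(
    "communication", "LHF", duration_ms=5.0, peak_freq_khz=14.0, fm_sweep="none",
    hf_component_gain=0.7, hf_peak_khz=60.0,
)


def generate_call_audio(
    spec: CallClassSpec,
    fs_audio_hz: float = 250_000.0,
    rng=None,
    noise_level: float = 1e-3,
    pad_s: float = 0.002,
) -> tuple[np.ndarray, CallEvent]:
    """Synthesize one call embedded in low-level noise.

    Returns the waveform (normalized to [-1, 1]) and a CallEvent whose
    onset/offset bracket the cosine-tapered call energy.  A peak (or sweep
    edge, or LHF component) above 40% of the sampling rate is rejected:
    the audio rate must be at least 2.5x the highest call frequency.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    span_khz = min(6.0, 0.1 * spec.peak_freq_khz) if spec.fm_sweep == "down" else 0.0
    top_khz = max(spec.peak_freq_khz + span_khz / 2,
                  spec.hf_peak_khz if spec.hf_component_gain > 0 else 0)
    if fs_audio_hz < 2.5 * top_khz * 1e3:
        raise ValueError(
            f"peak frequency {top_khz:.1f} kHz too close to Nyquist at "
            f"fs={fs_audio_hz:.0f} Hz (need fs >= 2.5x peak)"
        )
    n = max(8, int(round(spec.duration_ms * 1e-3 * fs_audio_hz)))
    t = np.arange(n) / fs_audio_hz
    f0 = spec.peak_freq_khz * 1e3
    if spec.fm_sweep == "down":
        sweep = span_khz * 1e3
        finst = f0 + sweep / 2 - sweep * t / t[-1]
        phase = 2 * np.pi * np.cumsum(finst) / fs_audio_hz
    else:
        phase = 2 * np.pi * f0 * t
    call = np.sin(phase)
    if spec.hf_component_gain > 0:
        call = call + spec.hf_component_gain * np.sin(2 * np.pi * spec.hf_peak_khz * 1e3 * t)
    taper = np.hanning(2 * (n // 4))
    window = np.ones(n)
    half = n // 4
    window[:half] = taper[:half]
    window[-half:] = taper[-half:]
    call *= window
    pad = int(round(pad_s * fs_audio_hz))
    wave = np.concatenate([np.zeros(pad), call, np.zeros(pad)])
    wave += noise_level * rng.standard_normal(wave.size)
    wave *= 0.9 / np.max(np.abs(wave))
    event = CallEvent(onset_s=pad / fs_audio_hz, offset_s=(pad + n) / fs_audio_hz)
    return wave, event


# ---------------------------------------------------------------------------
# session structure tables

@dataclass(frozen=True)
class BurstSpec:
    """A class/region/depth-specific band-limited burst around call onset."""

    call_class: str
    region: str  # 'FAF' | 'CN'
    depth_range_um: tuple[float, float]
    band_hz: tuple[float, float]
    window_s: tuple[float, float]  # relative to call onset
    gain: float  # peak amplitude in background-std units

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("burst gain must be >= 0")
        if not (1.0 <= self.band_hz[0] < self.band_hz[1] <= 90.0):
            raise ValueError(f"burst band {self.band_hz} outside 1-90 Hz")
        if not (-0.5 <= self.window_s[0] < self.window_s[1] <= 0.5):
            raise ValueError("burst window must lie within +/-500 ms of onset")


@dataclass(frozen=True)
class CoherenceSpec:
    """A shared FAF-CN band component with class-dependent timing and lag."""

    call_class: str
    band_hz: tuple[float, float]
    window_s: tuple[float, float]
    lag_ms: float  # CN lags FAF by this much
    strength: float

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("coherence strength must be >= 0")
        if not (-0.5 <= self.window_s[0] < self.window_s[1] <= 0.5):
            raise ValueError("coherence window must lie within +/-500 ms")


@dataclass(frozen=True)
class SpikeCouplingSpec:
    """Von Mises spike-phase coupling to one LFP band."""

    band_hz: tuple[float, float] = (4.0, 8.0)
    kappa: float = 2.0
    preferred_phase: float = np.pi
    base_rate_hz: float = 20.0
    evoked_gain: float = 1.0  # multiplicative rate elevation post-call

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.base_rate_hz < 0:
            raise ValueError("base rate must be >= 0")


def default_burst_table() -> list[BurstSpec]:
    """Study conditions: pre-call gamma biased to echolocation (striatum and
    deep FAF), pre-call beta biased to communication."""
    return [
        BurstSpec("echolocation", "CN", (0.0, 2000.0), (50.0, 80.0), (-0.25, -0.05), 1.5),
        BurstSpec("echolocation", "FAF", (400.0, 800.0), (30.0, 80.0), (-0.25, -0.05), 1.5),
        BurstSpec("communication", "FAF", (50.0, 800.0), (12.0, 30.0), (-0.30, -0.05), 1.2),
        BurstSpec("communication", "CN", (0.0, 2000.0), (12.0, 30.0), (-0.30, -0.05), 1.2),
    ]


def default_coherence_table() -> list[CoherenceSpec]:
    """Theta coherence pre-onset for communication, late (>250 ms) post-onset
    for echolocation, CN lagging FAF by 10 ms."""
    return [
        CoherenceSpec("communication", (4.0, 8.0), (-0.35, -0.05), 10.0, 1.5),
        CoherenceSpec("echolocation", (4.0, 8.0), (0.27, 0.45), 10.0, 1.5),
    ]


@dataclass
class SessionConfig:
    """Full parameterization of one synthetic session."""

    n_faf_channels: int = 16  # depths 50-800 um in 50-um steps
    n_cn_channels: int = 4  # 200-um spacing
    fs_neural_hz: float = 20_000.0
    fs_audio_hz: float = 250_000.0
    n_calls_per_class: int = 30
    isolation_fraction: float = 0.8
    lhf_fraction: float = 0.25
    burst_table: list[BurstSpec] = field(default_factory=default_burst_table)
    coherence_table: list[CoherenceSpec] = field(default_factory=default_coherence_table)
    spike_coupling: SpikeCouplingSpec = field(default_factory=SpikeCouplingSpec)
    alpha: float = 1.0  # 1/f^alpha background exponent
    background_std: float = 1.0
    noise_floor_std: float = 0.05  # extra wideband noise on top of the 1/f floor
    # trough depth of inserted spike waveforms; the 1/f background leaves
    # ~0.4 z-units of noise in the 300-3,000 Hz band, so 5 gives ~12 MADs
    spike_amplitude: float = 5.0
    evoked_gain_lfp: float = 1.0  # deep-FAF post-call deflection amplitude
    evoked_depth_um: float = 400.0
    echolocation_spec: CallClassSpec = ECHOLOCATION_SPEC
    communication_spec: CallClassSpec = COMMUNICATION_LF_SPEC
    communication_lhf_spec: CallClassSpec = COMMUNICATION_LHF_SPEC
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_calls_per_class < 1:
            raise ValueError("need at least one call per class")
        if not 0.0 <= self.isolation_fraction <= 1.0:
            raise ValueError("isolation_fraction must be in [0, 1]")
        for spec in self.burst_table:
            if spec.gain < 0:
                raise ValueError("all burst gains must be >= 0")

    def channel_meta(self):
        import pandas as pd

        rows = [
            {"structure": "FAF", "depth_um": 50.0 * (i + 1)}
            for i in range(self.n_faf_channels)
        ] + [
            {"structure": "CN", "depth_um": 200.0 * (i + 1)}
            for i in range(self.n_cn_channels)
        ]
        return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Everything needed to audit (and regenerate) a synthetic session."""

    config: SessionConfig
    events: list[CallEvent]
    rng_seed: int

    def to_json(self, path) -> None:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {"__class__": type(obj).__name__, **dataclasses.asdict(obj)}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            raise TypeError(f"not serializable: {type(obj)}")

        with open(path, "w") as f:
            json.dump(
                {
                    "rng_seed": self.rng_seed,
                    "config": dataclasses.asdict(self.config),
                    "events": [dataclasses.asdict(e) for e in self.events],
                },
                f,
                default=encode,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as f:
            raw = json.load(f)
        cfg = raw["config"]
        cfg["burst_table"] = [BurstSpec(**{**b, "depth_range_um": tuple(b["depth_range_um"]),
                                           "band_hz": tuple(b["band_hz"]),
                                           "window_s": tuple(b["window_s"])})
                              for b in cfg["burst_table"]]
        cfg["coherence_table"] = [CoherenceSpec(**{**c, "band_hz": tuple(c["band_hz"]),
                                                   "window_s": tuple(c["window_s"])})
                                  for c in cfg["coherence_table"]]
        cfg["spike_coupling"] = SpikeCouplingSpec(
            **{**cfg["spike_coupling"],
               "band_hz": tuple(cfg["spike_coupling"]["band_hz"])}
        )
        for key in ("echolocation_spec", "communication_spec", "communication_lhf_spec"):
            cfg[key] = CallClassSpec(**cfg[key])
        events = [CallEvent(**e) for e in raw["events"]]
        return cls(config=SessionConfig(**cfg), events=events, rng_seed=raw["rng_seed"])


@dataclass
class SessionResult:
    audio: np.ndarray | None
    fs_audio_hz: float
    recording: NeuralRecording
    spike_trains: list[SpikeTrain]
    events: list[CallEvent]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# primitives

def pink_noise(n: int, fs: float, alpha: float = 1.0, rng=None, std: float = 1.0
               ) -> np.ndarray:
    """1/f^alpha noise by FFT spectral shaping of white Gaussian noise."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x * (std / sd) if sd > 0 else x


def generate_phase_locked_spikes(
    phase: np.ndarray,
    fs: float,
    kappa: float,
    preferred_phase: float,
    base_rate_hz: float,
    rng=None,
    rate_mod: np.ndarray | None = None,
) -> np.ndarray:
    """Spike times from a phase-modulated inhomogeneous Poisson process.

    Intensity lambda(t) = base_rate * exp(kappa*cos(phase(t) - preferred))
    / I0(kappa), optionally multiplied by ``rate_mod`` (same length as
    ``phase``; e.g. a post-call evoked elevation).  Sampling is by thinning
    of a homogeneous Poisson process at the intensity maximum — exact and
    seedable.  As n grows the spike-phase histogram converges to
    von Mises(preferred_phase, kappa); kappa = 0 is a homogeneous process.
    An empty phase series yields an empty train.
    """
    phase = np.asarray(phase, dtype=float)
    if phase.size == 0:
        return np.empty(0)
    if kappa < 0 or base_rate_hz < 0:
        raise ValueError("kappa and base_rate must be >= 0")
    if base_rate_hz == 0:
        return np.empty(0)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    duration = phase.size / fs
    mod_max = float(np.max(rate_mod)) if rate_mod is not None else 1.0
    lam_max = base_rate_hz * np.exp(kappa) / i0(kappa) * mod_max
    n_cand = rng.poisson(lam_max * duration)
    if n_cand == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(0, duration, n_cand))
    idx = np.minimum((cand * fs).astype(int), phase.size - 1)
    lam = base_rate_hz * np.exp(kappa * np.cos(phase[idx] - preferred_phase)) / i0(kappa)
    if rate_mod is not None:
        lam = lam * np.asarray(rate_mod, dtype=float)[idx]
    keep = rng.uniform(0, lam_max, n_cand) < lam
    times = cand[keep]
    return np.unique(times)  # strictly increasing


def _gauss_burst(time: np.ndarray, window_s: tuple[float, float], freq_hz: float,
                 phase0: float, gain: float) -> np.ndarray:
    """Gaussian-windowed sinusoid occupying ``window_s`` on ``time``."""
    t0, t1 = window_s
    tc, sigma = (t0 + t1) / 2.0, (t1 - t0) / 4.0
    env = np.exp(-0.5 * ((time - tc) / sigma) ** 2)
    env[(time < t0 - sigma) | (time > t1 + sigma)] = 0.0
    return gain * env * np.cos(2 * np.pi * freq_hz * time + phase0)


def _spike_waveform(fs: float, amplitude: float) -> np.ndarray:
    """Biphasic extracellular spike: dominant negative trough, ~0.5 ms."""
    t = np.arange(int(round(1.2e-3 * fs))) / fs
    tc = t[-1] / 3
    w = -np.exp(-0.5 * ((t - tc) / 1.2e-4) ** 2) + 0.35 * np.exp(
        -0.5 * ((t - tc - 3.5e-4) / 2.2e-4) ** 2
    )
    return amplitude * w / np.max(np.abs(w))


def _evoked_waveform(time: np.ndarray, gain: float) -> np.ndarray:
    """Deterministic post-onset deflection (damped 6-Hz oscillation)."""
    post = np.clip(time, 0, None)
    wave = gain * np.exp(-post / 0.08) * np.sin(2 * np.pi * 6.0 * post)
    wave[time <= 0] = 0.0
    return wave


# ---------------------------------------------------------------------------
# call schedule

def _schedule_calls(config: SessionConfig, rng) -> list[dict]:
    """Place calls on the timeline honoring the isolation fraction."""
    specs = []
    for _ in range(config.n_calls_per_class):
        specs.append(config.echolocation_spec)
    for _ in range(config.n_calls_per_class):
        if rng.random() < config.lhf_fraction:
            specs.append(config.communication_lhf_spec)
        else:
            specs.append(config.communication_spec)
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]
    placed = []
    cursor = 0.6
    i = 0
    while i < len(specs):
        spec = specs[i]
        placed.append({"spec": spec, "onset_s": cursor})
        dur = spec.duration_ms * 1e-3
        pair = (rng.random() > config.isolation_fraction) and (i + 1 < len(specs))
        if pair:  # follower inside the post-window: first call contaminated_post
            gap = rng.uniform(0.15, 0.35)
            follower = specs[i + 1]
            placed.append({"spec": follower, "onset_s": cursor + dur + gap})
            cursor += dur + gap + follower.duration_ms * 1e-3
            i += 2
        else:
            cursor += dur
            i += 1
        cursor += rng.uniform(1.05, 1.3)
    return placed


# ---------------------------------------------------------------------------
# session generation

def generate_session(config: SessionConfig, with_audio: bool = True) -> SessionResult:
    """Generate a full synthetic session (audio, raw neural traces, spikes).

    Deterministic given ``config`` (identical seed => bit-identical
    arrays).  Neural traces are channels x samples at ``fs_neural_hz``; the
    spike trains returned are the ground-truth times actually inserted into
    the wideband traces.
    """
    master = np.random.SeedSequence(config.rng_seed)
    rng_sched, rng_neural, rng_spikes, rng_audio = [
        np.random.default_rng(s) for s in master.spawn(4)
    ]
    placed = _schedule_calls(config, rng_sched)
    last = placed[-1]
    total_s = last["onset_s"] + last["spec"].duration_ms * 1e-3 + 0.6
    fs = config.fs_neural_hz
    n_samples = int(round(total_s * fs))
    meta = config.channel_meta()
    n_ch = len(meta)

    traces = np.empty((n_ch, n_samples))
    for ch in range(n_ch):
        traces[ch] = pink_noise(n_samples, fs, config.alpha, rng_neural,
                                std=config.background_std)
        traces[ch] += config.noise_floor_std * rng_neural.standard_normal(n_samples)

    win_margin = 0.6
    seg_n = int(round(2 * win_margin * fs))
    seg_time = np.arange(seg_n) / fs - win_margin

    structures = meta["structure"].to_numpy()
    depths = meta["depth_um"].to_numpy(float)

    for call in placed:
        onset = call["onset_s"]
        label = call["spec"].class_label
        i0 = int(round((onset - win_margin) * fs))
        sl = slice(max(i0, 0), min(i0 + seg_n, n_samples))
        toff = slice(sl.start - i0, sl.start - i0 + (sl.stop - sl.start))
        # class/region/depth-dependent bursts (phase random per trial)
        for spec in config.burst_table:
            if spec.call_class != label or spec.gain == 0:
                continue
            phase0 = rng_neural.uniform(0, 2 * np.pi)
            freq = (spec.band_hz[0] + spec.band_hz[1]) / 2.0
            burst = _gauss_burst(seg_time, spec.window_s, freq, phase0, spec.gain)
            for ch in range(n_ch):
                if structures[ch] != spec.region:
                    continue
                if not (spec.depth_range_um[0] <= depths[ch] <= spec.depth_range_um[1]):
                    continue
                traces[ch, sl] += burst[toff]
        # shared inter-areal component (same phase, CN lagged)
        for spec in config.coherence_table:
            if spec.call_class != label or spec.strength == 0:
                continue
            phase0 = rng_neural.uniform(0, 2 * np.pi)
            freq = (spec.band_hz[0] + spec.band_hz[1]) / 2.0
            comp_faf = _gauss_burst(seg_time, spec.window_s, freq, phase0, spec.strength)
            lag = spec.lag_ms * 1e-3
            comp_cn = _gauss_burst(seg_time - lag, spec.window_s, freq, phase0,
                                   spec.strength)
            for ch in range(n_ch):
                comp = comp_faf if structures[ch] == "FAF" else comp_cn
                traces[ch, sl] += comp[toff]
        # deterministic evoked deflection, depth-scaled, deep FAF + weak CN
        evoked = _evoked_waveform(seg_time, config.evoked_gain_lfp)
        for ch in range(n_ch):
            if structures[ch] == "FAF" and depths[ch] >= config.evoked_depth_um:
                scale = np.clip((depths[ch] - config.evoked_depth_um + 100) / 400, 0, 1)
                traces[ch, sl] += evoked[toff] * scale
            elif structures[ch] == "CN":
                traces[ch, sl] += 0.4 * evoked[toff]

    # --- spikes: von Mises coupling to the band phase of each channel's LFP
    from .spikephase import instantaneous_phase

    coupling = config.spike_coupling
    onsets = np.array([c["onset_s"] for c in placed])
    rate_mod = np.ones(n_samples)
    if coupling.evoked_gain > 0:
        for onset in onsets:
            j0 = int(round(onset * fs))
            j1 = min(n_samples, j0 + int(round(0.1 * fs)))
            rate_mod[j0:j1] *= 1.0 + coupling.evoked_gain
    spike_trains = []
    wave = _spike_waveform(fs, config.spike_amplitude)
    trough = int(np.argmin(wave))
    for ch in range(n_ch):
        phase = instantaneous_phase(traces[ch], fs, coupling.band_hz)
        times = generate_phase_locked_spikes(
            phase, fs, coupling.kappa, coupling.preferred_phase,
            coupling.base_rate_hz, rng_spikes, rate_mod=rate_mod,
        )
        # enforce a 1.5-ms minimum separation so detection lockout is fair
        if times.size:
            keep = np.concatenate([[True], np.diff(times) > 1.5e-3])
            times = times[keep]
        for t in times:
            j = int(round(t * fs)) - trough
            if 0 <= j and j + wave.size <= n_samples:
                traces[ch, j : j + wave.size] += wave
        spike_trains.append(SpikeTrain(times_s=times, channel=ch,
                                       threshold_mad=np.nan))

    recording = NeuralRecording(traces=traces, fs_hz=fs, channel_meta=meta)

    # --- events with isolation flags from the actual schedule
    events = []
    for call in placed:
        spec = call["spec"]
        events.append(
            CallEvent(
                onset_s=call["onset_s"],
                offset_s=call["onset_s"] + spec.duration_ms * 1e-3,
                peak_freq_khz=spec.peak_freq_khz,
                class_label=spec.class_label,
                subclass=None if spec.subclass == "none" else spec.subclass,
            )
        )
    events = select_isolated(events, recording_bounds=(0.0, total_s))

    # --- audio track
    audio = None
    if with_audio:
        fs_a = config.fs_audio_hz
        audio = 1e-3 * rng_audio.standard_normal(int(round(total_s * fs_a)))
        for call, ev in zip(placed, events):
            core, _ = generate_call_audio(call["spec"], fs_a, rng_audio, pad_s=0.0,
                                          noise_level=0.0)
            j = int(round(ev.onset_s * fs_a))
            end = min(j + core.size, audio.size)
            audio[j:end] += core[: end - j]
        audio = audio * (0.9 / np.max(np.abs(audio)))

    gt = GroundTruth(config=config, events=events, rng_seed=config.rng_seed)
    return SessionResult(
        audio=audio,
        fs_audio_hz=config.fs_audio_hz,
        recording=recording,
        spike_trains=spike_trains,
        events=events,
        ground_truth=gt,
    )


def generate_condition_epochs(
    config: SessionConfig,
    n_trials_per_class: int,
    fs: float = 1000.0,
    window: tuple[float, float] = (-0.5, 0.5),
    rng=None,
) -> EpochSet:
    """Directly synthesize call-aligned 1-kHz epochs (no continuous traces).

    Statistically equivalent to conditioning a full session (same 1/f
    background, burst, coherence and evoked structure per trial) but
    generated on the epoch grid; the fast path for analyses that only need
    EpochSets.  Trials alternate classes; labels mark every trial isolated.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    meta = config.channel_meta()
    n_ch = len(meta)
    time = np.arange(int(round(window[0] * fs)), int(round(window[1] * fs)) + 1) / fs
    n_t = time.size
    structures = meta["structure"].to_numpy()
    depths = meta["depth_um"].to_numpy(float)
    labels = (["echolocation"] * n_trials_per_class
              + ["communication"] * n_trials_per_class)
    data = np.empty((len(labels), n_ch, n_t))
    evoked = _evoked_waveform(time, config.evoked_gain_lfp)
    for ti, label in enumerate(labels):
        for ch in range(n_ch):
            data[ti, ch] = pink_noise(n_t, fs, config.alpha, rng,
                                      std=config.background_std)
        for spec in config.burst_table:
            if spec.call_class != label or spec.gain == 0:
                continue
            phase0 = rng.uniform(0, 2 * np.pi)
            freq = (spec.band_hz[0] + spec.band_hz[1]) / 2.0
            burst = _gauss_burst(time, spec.window_s, freq, phase0, spec.gain)
            for ch in range(n_ch):
                if structures[ch] == spec.region and (
                    spec.depth_range_um[0] <= depths[ch] <= spec.depth_range_um[1]
                ):
                    data[ti, ch] += burst
        for spec in config.coherence_table:
            if spec.call_class != label or spec.strength == 0:
                continue
            phase0 = rng.uniform(0, 2 * np.pi)
            freq = (spec.band_hz[0] + spec.band_hz[1]) / 2.0
            comp_faf = _gauss_burst(time, spec.window_s, freq, phase0, spec.strength)
            comp_cn = _gauss_burst(time - spec.lag_ms * 1e-3, spec.window_s, freq,
                                   phase0, spec.strength)
            for ch in range(n_ch):
                data[ti, ch] += comp_faf if structures[ch] == "FAF" else comp_cn
        for ch in range(n_ch):
            if structures[ch] == "FAF" and depths[ch] >= config.evoked_depth_um:
                scale = np.clip((depths[ch] - config.evoked_depth_um + 100) / 400, 0, 1)
                data[ti, ch] += evoked * scale
            elif structures[ch] == "CN":
                data[ti, ch] += 0.4 * evoked

    import pandas as pd

    frame = pd.DataFrame(
        {
            "onset_s": np.arange(len(labels), dtype=float),
            "class": labels,
            "subclass": [None] * len(labels),
            "isolated": True,
            "contaminated_post": False,
        }
    )
    return EpochSet(data=data, time=time, fs_hz=fs, labels=frame, channel_meta=meta)


# ---------------------------------------------------------------------------
# WAV I/O (PCM 16-bit)

def write_wav(path, waveform: np.ndarray, fs_hz: float) -> None:
    from scipy.io import wavfile

    x = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(fs_hz), (x * 32767).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, float]:
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data.astype(float) / 32767.0
    return data, float(fs)
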