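"""Shared configuration for the numbered analysis scripts.

One scaled synthetic session (the "study session") is used throughout:
4 frontal (FAF) depths, 2 striatal (CN) channels, 40 calls per class at
20 kHz, with the default injected structure (pre-call gamma biased to
echolocation, pre-call beta to communication, class-dependent theta
coherence timing, theta-locked spiking).  Epoch-pool analyses that need
hundreds of epochs per class use the epoch-level generator at the same
parameters.  Text tables go to results/, bulky regenerable artifacts
(audio, raw traces, epoch HDF5, figures) to scratch/.
"""

from pathlib import Path

from vocolock.synth import SessionConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis"

SESSION_SEED = 2026
SESSION = SessionConfig(
    n_faf_channels=4,
    n_cn_channels=2,
    n_calls_per_class=40,
    isolation_fraction=0.8,
    rng_seed=SESSION_SEED,
)

# multitaper parameters for all locked-spectral analyses (desk scale:
# 5-ms hop, 512-point FFT; window/TW/K at the standard values)
MT = dict(fs=1000.0, win_s=0.25, step_s=0.005, TW=2, K=3, nfft=512,
          time_offset_s=-0.5)

N_RAND = 1000
K_AVG = 50
N_EPOCH_POOL = 400  # epochs per class for randomization-trial analyses


def ensure_dirs() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
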