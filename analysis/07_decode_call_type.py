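#!/usr/bin/env python
"""Decode call type from pre-vocalization band power with the rbf SVM.

Builds randomization-trial band-power feature sets per band for the first
striatal channel (500 + 500 per class train, same held out), trains once
without standardization, and reports held-out accuracy, 10-fold CV error,
and the label-shuffle control.  Writes results/decoding.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import K_AVG, MT, N_EPOCH_POOL, RESULTS, SESSION, ensure_dirs

from vocolock.bands import BANDS
from vocolock.decoding import (
    FeatureSet,
    band_power_features,
    crossvalidate,
    evaluate,
    shuffled_label_control,
    train_decoder,
)
from vocolock.spectral import build_randomization_trials, multitaper_power
from vocolock.synth import generate_condition_epochs

N_RAND = 1000  # 500 train + 500 held out per class


def main() -> None:
    ensure_dirs()
    epochs = generate_condition_epochs(SESSION, N_EPOCH_POOL,
                                       rng=SESSION.rng_seed + 2)
    meta = epochs.channel_meta
    cn = next(i for i in range(len(meta)) if meta.iloc[i]["structure"] == "CN")
    mt = dict(MT, step_s=0.002)

    power = {}
    for cond in ("echolocation", "communication"):
        rt = build_randomization_trials(epochs.condition(cond).data[:, cn, :],
                                        n_rand=N_RAND, k=K_AVG, rng=11)
        power[cond] = multitaper_power(rt.trials, **mt)

    rows = []
    half = N_RAND // 2
    for band in BANDS:
        feats = {
            cond: band_power_features(p, t, f, [cond] * N_RAND, band, window="pre").X
            for cond, (p, t, f) in power.items()
        }
        train = FeatureSet(
            X=np.vstack([feats["echolocation"][:half], feats["communication"][:half]]),
            y=np.array(["echolocation"] * half + ["communication"] * half),
            band=band, channel=cn,
        )
        test = FeatureSet(
            X=np.vstack([feats["echolocation"][half:], feats["communication"][half:]]),
            y=train.y.copy(), band=band, channel=cn,
        )
        model = train_decoder(train)
        rows.append({
            "channel": cn, "band": band,
            "accuracy_pct": evaluate(model, test),
            "cv_error": crossvalidate(train, folds=10, seed=0),
            "shuffled_accuracy_pct": shuffled_label_control(train, test, seed=1),
        })
        print(f"{band:>10}: accuracy {rows[-1]['accuracy_pct']:5.1f}%  "
              f"cv error {rows[-1]['cv_error']:.3f}  "
              f"shuffled {rows[-1]['shuffled_accuracy_pct']:5.1f}%")
    pd.DataFrame(rows).to_csv(RESULTS / "decoding.csv", index=False)


if __name__ == "__main__":
    main()
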