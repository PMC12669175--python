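"""Reproducible desk-scale experiments.

These bundle the library stages into the experiments the test-suite and the
reproduction script run: the end-to-end smoke training on a synthetic
cohort, and the multi-scanner harmonization spread measurement.  Problem
sizes are chosen so the whole protocol runs on a single CPU core in minutes:
phantoms are generated at 64 x 64 x 12 voxels (0.47 x 0.47 x 6.5 mm) and
resampled in-plane by a factor of two before training, and the network is
the two-layer reduced-width variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .objectives_training import TrainConfig, kfold_split, run_training
from .preprocess_harmonize import GeometrySpec, harmonization_spec, harmonize, resample
from .segmentation_network import build_network, small_network_spec
from .synthetic_data import PhantomSpec, generate_cohort

__all__ = ["SmokeResult", "desk_scale_smoke", "harmonization_spread"]

DESK_SPACING = (0.94, 0.94, 6.5)


@dataclass
class SmokeResult:
    seed: int
    val_dice: float
    final_train_loss: float
    epochs: int
    n_train: int
    n_val: int


def desk_scale_smoke(
    seed: int,
    n_subjects: int = 8,
    epochs: int = 25,
    channels: tuple[int, int] = (8, 16),
    d_state: int = 4,
) -> SmokeResult:
    """Generate -> preprocess -> train -> predict -> evaluate, one seed.

    Trains the reduced two-layer network on 6 phantoms and reports the mean
    validation Dice on the 2 held-out phantoms of the first fold.
    """
    cohort = generate_cohort(n_subjects, PhantomSpec(seed=100 + seed))
    geo = GeometrySpec(target_spacing=DESK_SPACING)
    pairs = []
    for vol, mask, _ in cohort:
        v = resample(vol, geo).data
        y = resample(mask, geo, is_label=True).data.astype(np.uint8)
        pairs.append((v, y))
    train_idx, val_idx = kfold_split(n_subjects, n_subjects // 2, seed=seed)[0]
    net = build_network(
        small_network_spec(channels=channels, d_state=d_state), seed=seed
    )
    tc = TrainConfig(epochs=epochs, seed=seed)
    res = run_training(
        net,
        [pairs[i] for i in train_idx],
        tc,
        val_data=[pairs[i] for i in val_idx],
    )
    last = res.history[-1]
    return SmokeResult(
        seed=seed,
        val_dice=last["val_dice"],
        final_train_loss=last["train_loss"],
        epochs=epochs,
        n_train=len(train_idx),
        n_val=len(val_idx),
    )


def harmonization_spread(seed: int, n_subjects: int = 8) -> dict[str, float]:
    """Cross-scanner mean-intensity spread before/after harmonization."""
    cohort = generate_cohort(n_subjects, PhantomSpec(seed=seed))
    vols = [v for v, _, _ in cohort]
    spec = harmonization_spec(vols[0])
    before = np.array([v.data.mean() for v in vols])
    after = np.array([harmonize(v, spec).data.mean() for v in vols])
    sd_before = float(before.std())
    sd_after = float(after.std())
    return {
        "spread_before": sd_before,
        "spread_after": sd_after,
        "reduction_pct": 100.0 * (1.0 - sd_after / sd_before),
    }
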