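"""Combined Dice + cross-entropy objective, deep supervision, and training.

The loss on binary voxel labels ``y`` with predicted foreground
probabilities ``p`` is

    L_total = 1/2 L_CE + 1/2 L_Dice
    L_CE    = -mean( y log p + (1 - y) log(1 - p) )
    L_Dice  = 1 - (2 sum(p y) + eps) / (sum p + sum y + eps)

supervised at every decoder resolution with exponentially decaying weights
1/2^i (i = 0 at full resolution), normalized to sum to one.  Probabilities
are clamped away from {0, 1} in the cross-entropy; the Dice term is computed
on the foreground class only, which is what makes the objective usable under
the extreme class imbalance of small bright lesions.

Training uses AdamW (weight decay 0.05) with cosine learning-rate decay from
1e-3, per-volume steps, per-volume z-scoring, optional in-plane flip
augmentation, k-fold cross-validation, and a pretrain -> fine-tune path that
loads a checkpoint and restarts the schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import AdamW, Tensor
from .segmentation_network import (
    Network,
    NetworkSpec,
    SegmentationOutput,
    _zscore,
    build_network,
    save_checkpoint,
)

__all__ = [
    "LossConfig",
    "TrainConfig",
    "dice_loss",
    "ce_loss",
    "total_loss",
    "cosine_lr",
    "kfold_split",
    "run_training",
    "TrainingResult",
]


@dataclass
class LossConfig:
    ce_weight: float = 0.5
    dice_weight: float = 0.5
    epsilon: float = 1e-6
    clamp: float = 1e-7

    def __post_init__(self):
        if self.ce_weight < 0 or self.dice_weight < 0:
            raise ValueError("loss weights must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class TrainConfig:
    epochs: int = 20
    lr: float = 1e-3
    weight_decay: float = 0.05
    seed: int = 0
    folds: int = 5
    augment_flips: bool = False
    fine_tune_from: str | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


# ---------------------------------------------------------------------------
# Loss terms (numpy, probability inputs)


def dice_loss(p: np.ndarray, y: np.ndarray, epsilon: float = 1e-6) -> float:
    """Soft Dice loss on foreground probabilities."""
    p = np.asarray(p, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    return float(1.0 - (2.0 * (p * y).sum() + epsilon) / (p.sum() + y.sum() + epsilon))


def ce_loss(p: np.ndarray, y: np.ndarray, clamp: float = 1e-7) -> float:
    """Mean binary cross-entropy with probability clamping."""
    p = np.clip(np.asarray(p, dtype=float).reshape(-1), clamp, 1.0 - clamp)
    y = np.asarray(y, dtype=float).reshape(-1)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _nearest_downsample(y: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Nearest-neighbor label down-sampling to an exact target shape."""
    idx = tuple(
        (np.arange(t) * s) // t for s, t in zip(y.shape, shape)
    )
    return y[np.ix_(*idx)]


def _level_loss_t(logits: Tensor, y: np.ndarray, cfg: LossConfig) -> Tensor:
    """Differentiable 1/2 CE + 1/2 Dice on 2-class logits (2, X, Y, Z)."""
    if logits.shape[0] != 2:
        raise ValueError("combined loss is defined for binary (2-class) logits")
    c = np.max(logits.data, axis=0, keepdims=True)  # constant shift, exact
    lse = ((logits - c).exp().sum(axis=0, keepdims=True)).log() + c
    logp = logits - lse                                  # log-softmax
    logp1 = ad_slice(logp, 1)
    logp0 = ad_slice(logp, 0)
    yf = y.astype(float)
    ce = -(logp1 * yf + logp0 * (1.0 - yf)).mean()
    p1 = logp1.exp()
    eps = cfg.epsilon
    dice = 1.0 - ((p1 * yf).sum() * 2.0 + eps) / (p1.sum() + float(yf.sum()) + eps)
    return ce * cfg.ce_weight + dice * cfg.dice_weight


def ad_slice(t: Tensor, channel: int) -> Tensor:
    from .autodiff import crop

    return crop(t, [slice(channel, channel + 1)] + [slice(None)] * (t.ndim - 1))


def total_loss_t(
    logits: Tensor, aux: list[Tensor], target: np.ndarray, cfg: LossConfig
) -> Tensor:
    """Deep-supervised combined loss on Tensor logits (training path)."""
    levels = [logits] + list(aux)
    weights = np.array([0.5**i for i in range(len(levels))])
    weights /= weights.sum()
    out = None
    for w, lv in zip(weights, levels):
        yl = _nearest_downsample(target, lv.shape[1:])
        term = _level_loss_t(lv, yl, cfg) * float(w)
        out = term if out is None else out + term
    return out


def total_loss(
    outputs: SegmentationOutput, target: np.ndarray, cfg: LossConfig | None = None
) -> float:
    """Deep-supervised combined loss on a segmentation output (evaluation)."""
    cfg = cfg or LossConfig()
    return total_loss_t(
        Tensor(outputs.logits),
        [Tensor(a) for a in outputs.aux_logits],
        np.asarray(target),
        cfg,
    ).item()


# ---------------------------------------------------------------------------
# Schedule and folds


def cosine_lr(epoch: int, epochs: int, lr0: float) -> float:
    """Cosine decay from ``lr0`` at epoch 0 to 0 at the final epoch."""
    if epochs <= 1:
        return lr0
    return lr0 * 0.5 * (1.0 + math.cos(math.pi * epoch / (epochs - 1)))


def kfold_split(
    n: int, k: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint validation folds covering all ``n`` subjects exactly once."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= folds <= n, got k={k}, n={n}")
    idx = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(idx, k)
    return [
        (np.sort(np.concatenate(folds[:i] + folds[i + 1 :])), np.sort(folds[i]))
        for i in range(k)
    ]


# ---------------------------------------------------------------------------
# Training loop


@dataclass
class TrainingResult:
    history: list[dict] = field(default_factory=list)
    checkpoint: str | None = None

    @property
    def final_loss(self) -> float:
        return self.history[-1]["train_loss"]


def run_training(
    net: Network,
    data: list[tuple[np.ndarray, np.ndarray]],
    tc: TrainConfig,
    loss_cfg: LossConfig | None = None,
    val_data: list[tuple[np.ndarray, np.ndarray]] | None = None,
    checkpoint_path: str | Path | None = None,
    log=None,
) -> TrainingResult:
    """Train on (volume, binary label) pairs with per-volume steps.

    Volumes are z-scored per channel once up front.  Raises on non-finite
    loss with the offending epoch/volume in the message.
    """
    from .evaluation_metrics import confusion, overlap_metrics

    loss_cfg = loss_cfg or LossConfig()
    rng = np.random.default_rng(tc.seed)
    prep = [(_as_channels(v), np.asarray(y)) for v, y in data]
    prep = [(_zscore(v), y) for v, y in prep]
    vprep = None
    if val_data:
        vprep = [(_zscore(_as_channels(v)), np.asarray(y)) for v, y in val_data]
    opt = AdamW(net.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)
    result = TrainingResult()
    for epoch in range(tc.epochs):
        opt.lr = cosine_lr(epoch, tc.epochs, tc.lr)
        order = rng.permutation(len(prep))
        losses = []
        for j in order:
            v, y = prep[j]
            if tc.augment_flips:
                flips = [a + 1 for a in range(2) if rng.random() < 0.5]
                if flips:
                    v = np.flip(v, axis=flips).copy()
                    y = np.flip(y, axis=[a - 1 for a in flips]).copy()
            logits, aux = net.forward(Tensor(v))
            loss = total_loss_t(logits, aux, y, loss_cfg)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss {loss.item()} at epoch {epoch}, volume {j}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        rec = {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses))}
        if vprep is not None:
            dices = []
            for v, y in vprep:
                pred = np.argmax(net.segment(v).logits, axis=0)
                dices.append(overlap_metrics(confusion(pred, y)).dice)
            rec["val_dice"] = float(np.mean(dices))
        result.history.append(rec)
        if log:
            log(rec)
    if checkpoint_path is not None:
        save_checkpoint(net, checkpoint_path)
        result.checkpoint = str(checkpoint_path)
    return result


def train_kfold(
    spec: NetworkSpec,
    data: list[tuple[np.ndarray, np.ndarray]],
    tc: TrainConfig,
    loss_cfg: LossConfig | None = None,
    out_dir: str | Path | None = None,
) -> list[TrainingResult]:
    """k-fold cross-validation: one freshly seeded network per fold."""
    results = []
    for f, (tr, va) in enumerate(kfold_split(len(data), tc.folds, tc.seed)):
        net = build_network(spec, seed=tc.seed + f)
        ckpt = None
        if out_dir is not None:
            ckpt = Path(out_dir) / f"fold{f}.npz"
        results.append(
            run_training(
                net,
                [data[i] for i in tr],
                tc,
                loss_cfg,
                val_data=[data[i] for i in va],
                checkpoint_path=ckpt,
            )
        )
    return results


def _as_channels(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v[None] if v.ndim == 3 else v
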