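"""Training protocol for both segmentation networks.

Both U-Nets train the same way: binary cross-entropy loss, Adam at learning
rate 0.001, batch size 32, 60 epochs, with per-epoch loss and overlap metrics
(Dice, accuracy, precision, sensitivity, specificity) recorded on the train
and validation sets. Model evaluation uses repeated seeded 80:20 splits at
the subject level (no slice leakage between train and validation), reporting
per-repeat validation metrics and their means.

All metrics are computed by the quantify/metrics module on predictions
binarised at 0.5 — a single source of truth shared with inference.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import metrics as qm
from .nn.unet import UNet, UNetConfig, build_unet, forward_tiles
from .volume import BinaryMask

__all__ = ["TrainingConfig", "EpochRecord", "bce_loss", "train_model", "crossval",
           "CrossvalResult"]


@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    """Optimisation hyperparameters (defaults follow the training protocol)."""

    batch_size: int = 32
    learning_rate: float = 0.001
    epochs: int = 60
    threshold: float = 0.5       # binarisation threshold for logged metrics
    seed: int = 0
    split: float = 0.8           # train fraction of each 80:20 repeat
    repeats: int = 10
    log_metrics: bool = True     # per-epoch overlap metrics (loss is always logged)

    def __post_init__(self) -> None:
        if not (0 < self.split < 1):
            raise ValueError("split must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclasses.dataclass
class EpochRecord:
    epoch: int
    train: dict[str, float]
    val: dict[str, float] | None = None


EpochLog = list


_EPS = 1e-7


def bce_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean binary cross-entropy over all voxels; predictions clipped to
    [eps, 1-eps] so the loss stays finite."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    y = np.asarray(target, dtype=np.float64)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


def _evaluate(model: UNet, x: np.ndarray, y: np.ndarray, threshold: float) -> dict[str, float]:
    """Loss plus the five overlap metrics (micro, pooled over all voxels)."""
    probs = forward_tiles(model, x)
    pred = BinaryMask((probs >= threshold).astype(np.uint8).transpose(1, 2, 0), (1, 1, 1))
    truth = BinaryMask(np.asarray(y, dtype=np.uint8).transpose(1, 2, 0), (1, 1, 1))
    out = qm.all_metrics(pred, truth)
    out["loss"] = bce_loss(probs, y)
    return out


def train_model(
    model: UNet,
    data: tuple[np.ndarray, np.ndarray],
    cfg: TrainingConfig,
    val_data: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[UNet, EpochLog]:
    """Train a network on paired slices and masks, logging every epoch.

    ``data`` is (slices, masks), each shaped (N, H, W) with masks in {0, 1}.
    Shuffling and any stochastic behaviour derive from ``cfg.seed``; two runs
    with identical inputs and seed produce identical results.
    """
    from .nn.layers import Adam

    x, y = data
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    if x.shape != y.shape:
        raise ValueError(f"slices {x.shape} and masks {y.shape} differ")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, lr=cfg.learning_rate)
    log: EpochLog = []
    n = x.shape[0]
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x[idx]
            yb = y[idx][..., None]
            opt.zero_grad()
            logits = model.forward_logits(xb, train=True)
            probs = _sigmoid(logits)
            loss_grad = (probs - yb) / probs.size  # d(mean BCE)/d(logits)
            model.backward(loss_grad.astype(np.float32))
            opt.step()
            if not np.isfinite(logits).all():
                raise RuntimeError(
                    f"non-finite activations at epoch {epoch}; "
                    "reduce the learning rate or check the input scaling"
                )
            epoch_loss += bce_loss(probs[..., 0], yb[..., 0]) * len(idx)
        if cfg.log_metrics:
            rec = EpochRecord(epoch=epoch, train=_evaluate(model, x, y, cfg.threshold))
            if val_data is not None:
                rec.val = _evaluate(model, val_data[0].astype(np.float32),
                                    val_data[1].astype(np.float32), cfg.threshold)
        else:
            # cheap record: running loss over the epoch's own batches
            rec = EpochRecord(epoch=epoch, train={"loss": epoch_loss / n})
        if not np.isfinite(rec.train["loss"]):
            raise RuntimeError(f"NaN loss at epoch {epoch}")
        log.append(rec)
    return model, log


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclasses.dataclass
class CrossvalResult:
    """Per-repeat validation metrics of repeated 80:20 evaluation."""

    records: list[dict[str, float]]
    splits: list[tuple[list[int], list[int]]]  # (train idx, val idx) per repeat
    models: list = dataclasses.field(default_factory=list)  # if kept

    @property
    def means(self) -> dict[str, float]:
        keys = self.records[0].keys()
        return {k: float(np.mean([r[k] for r in self.records])) for k in keys}


def crossval(
    cases: Sequence[tuple[np.ndarray, np.ndarray]],
    unet_cfg: UNetConfig,
    train_cfg: TrainingConfig,
    keep_models: bool = False,
) -> CrossvalResult:
    """Repeated random 80:20 evaluation at the subject level.

    Each repeat draws a fresh seeded split of whole cases (a case's slices
    are never divided between train and validation), trains a freshly
    initialised network, and scores the five metrics on the held-out 20%.
    """
    n = len(cases)
    if n < 5:
        raise ValueError("need at least 5 cases for a non-empty 20% split")
    records: list[dict[str, float]] = []
    splits: list[tuple[list[int], list[int]]] = []
    models: list[UNet] = []
    for r in range(train_cfg.repeats):
        seed = int(np.random.SeedSequence([train_cfg.seed, r]).generate_state(1)[0]
                   % (2 ** 31))
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        n_train = max(1, min(n - 1, int(round(train_cfg.split * n))))
        tr, va = sorted(order[:n_train].tolist()), sorted(order[n_train:].tolist())
        splits.append((tr, va))
        x_tr = np.concatenate([cases[i][0] for i in tr])
        y_tr = np.concatenate([cases[i][1] for i in tr])
        x_va = np.concatenate([cases[i][0] for i in va])
        y_va = np.concatenate([cases[i][1] for i in va])
        model = build_unet(unet_cfg, seed=seed)
        rcfg = dataclasses.replace(train_cfg, seed=seed)
        model, _ = train_model(model, (x_tr, y_tr), rcfg)
        records.append(_evaluate(model, x_va.astype(np.float32),
                                 y_va.astype(np.float32), train_cfg.threshold))
        if keep_models:
            models.append(model)
    return CrossvalResult(records=records, splits=splits, models=models)
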