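"""Training loop with best-validation checkpointing, plus batched prediction.

Training uses mini-batch AdamW (decoupled weight decay) on the focal loss for
a fixed number of epochs; after every epoch the validation accuracy is
measured and the parameter state achieving the best value is kept.  Every
source of randomness (shuffling, dropout) is seeded, so two runs with the same
configuration produce identical logs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .arch import HIRDNet, HIRDNetConfig
from .nn.optim import AdamW
from .objectives import FocalLossConfig, beta_from_counts, focal_loss_graph

__all__ = ["TrainConfig", "TrainLog", "train", "predict",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 90
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    seed: int = 0
    checkpoint_metric: str = "val_accuracy"
    alpha: float = 2.0
    beta: str | list[float] = "auto"  # "auto" | "uniform" | explicit weights
    lr_schedule: str = "none"  # "none" | "cosine"
    max_steps: int | None = None  # cap on total gradient steps (smoke tests)

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.checkpoint_metric != "val_accuracy":
            raise ValueError("only val_accuracy checkpointing is supported")
        if self.lr_schedule not in ("none", "cosine"):
            raise ValueError("lr_schedule must be 'none' or 'cosine'")


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    step_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
        })


def _stack(image_set, input_size: int) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for obj, grade in image_set.items:
        arr = obj.pixels if hasattr(obj, "pixels") else np.asarray(obj)
        if arr.shape[0] != input_size or arr.shape[1] != input_size:
            raise ValueError(
                f"image is {arr.shape[0]}×{arr.shape[1]}, the model expects "
                f"{input_size}×{input_size}; run the enhancement pipeline first")
        xs.append(arr.astype(np.float32).transpose(2, 0, 1) / 255.0)
        ys.append(grade)
    return np.stack(xs), np.array(ys, dtype=np.int64)


def _accuracy_and_loss(model: HIRDNet, x, y, loss_cfg, batch_size: int):
    correct = 0
    losses = []
    onehot = np.eye(model.cfg.num_classes, dtype=np.float32)[y]
    for i in range(0, len(y), batch_size):
        probs = model(x[i : i + batch_size], train=False)
        pred = probs.data.argmax(axis=1)
        correct += int((pred == y[i : i + batch_size]).sum())
        from .objectives import focal_loss

        losses.append(focal_loss(probs.data, onehot[i : i + batch_size], loss_cfg)
                      * len(pred))
    return 100.0 * correct / len(y), float(np.sum(losses) / len(y))


def train(model: HIRDNet, train_set, val_set, cfg: TrainConfig = TrainConfig()):
    """Optimize ``model``; returns (best_state, TrainLog).

    ``best_state`` is the flat array mapping of the epoch with the highest
    validation accuracy (ties keep the earlier epoch) and is already loaded
    back into the model when training finishes.
    """
    if len(train_set.items) == 0 or len(val_set.items) == 0:
        raise ValueError("train and validation sets must be non-empty")
    x_tr, y_tr = _stack(train_set, model.cfg.input_size)
    x_va, y_va = _stack(val_set, model.cfg.input_size)
    n_classes = model.cfg.num_classes
    counts = np.bincount(y_tr, minlength=n_classes)
    if (counts == 0).any():
        warnings.warn(f"training set has empty classes: {np.nonzero(counts == 0)[0].tolist()}")
    if cfg.beta == "auto":
        beta = beta_from_counts(np.maximum(counts, 1))
    elif cfg.beta == "uniform":
        beta = None
    else:
        beta = np.asarray(cfg.beta, dtype=float)
    loss_cfg = FocalLossConfig(alpha=cfg.alpha, beta=beta)

    rng = np.random.default_rng(cfg.seed)
    model.reseed_dropout(cfg.seed + 1)
    opt = AdamW(model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    onehot_all = np.eye(n_classes, dtype=np.float32)[y_tr]

    log = TrainLog()
    best_state: dict[str, np.ndarray] | None = None
    steps = 0
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            opt.lr = cfg.learning_rate * 0.5 * (1 + np.cos(np.pi * epoch / cfg.epochs))
        order = rng.permutation(len(y_tr))
        epoch_losses = []
        for i in range(0, len(order), cfg.batch_size):
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                break
            idx = order[i : i + cfg.batch_size]
            probs = model(x_tr[idx], train=True)
            loss = focal_loss_graph(probs, onehot_all[idx], loss_cfg)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, step {steps}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            log.step_losses.append(float(loss.data))
            steps += 1
        tr_acc, tr_loss = _accuracy_and_loss(model, x_tr, y_tr, loss_cfg, cfg.batch_size)
        va_acc, va_loss = _accuracy_and_loss(model, x_va, y_va, loss_cfg, cfg.batch_size)
        log.train_loss.append(tr_loss)
        log.train_accuracy.append(tr_acc)
        log.val_loss.append(va_loss)
        log.val_accuracy.append(va_acc)
        if va_acc > log.best_val_accuracy or best_state is None:
            log.best_val_accuracy = va_acc
            log.best_epoch = epoch + 1
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        if cfg.max_steps is not None and steps >= cfg.max_steps:
            break
    model.load_state_arrays(best_state)
    return best_state, log


def predict(model: HIRDNet, image_set, batch_size: int = 32):
    """(predicted labels, class probabilities) for a labelled or unlabelled set."""
    from types import SimpleNamespace

    items = image_set.items if hasattr(image_set, "items") else [(im, 0) for im in image_set]
    x, _ = _stack(SimpleNamespace(items=items), model.cfg.input_size)
    probs = np.concatenate([
        model(x[i : i + batch_size], train=False).data for i in range(0, len(x), batch_size)
    ])
    return probs.argmax(axis=1), probs


def save_checkpoint(path, model: HIRDNet) -> None:
    """Single-file checkpoint: weights, batch-norm statistics and the config."""
    arrays = model.state_arrays()
    np.savez(path, __config__=np.frombuffer(model.cfg.to_json().encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> HIRDNet:
    with np.load(path) as data:
        cfg = HIRDNetConfig.from_json(bytes(data["__config__"]).decode())
        model = HIRDNet(cfg)
        model.load_state_arrays({k: data[k] for k in data.files if k != "__config__"})
    return model
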