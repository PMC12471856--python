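"""Activation functions and the multi-class focal loss.

The focal loss re-weights categorical cross-entropy by ``(1 - p_true)**alpha``
so well-classified samples contribute little, and by per-class weights
``beta_j`` to balance class contributions:

    L = -(1/N) Σ_i Σ_j  β_j (1 - f_j(x_i))^α  y_ij  log f_j(x_i)

With α = 0 and β_j = 1 it reduces exactly to cross-entropy.  The focusing
parameter defaults to α = 2, the canonical setting; β defaults to inverse
class-frequency weights normalized to mean one when training-class counts are
supplied, or to uniform weights otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.tensor import Tensor

__all__ = [
    "relu6",
    "hard_swish",
    "FocalLossConfig",
    "beta_from_counts",
    "focal_loss",
    "focal_loss_graph",
]

#: probabilities are clipped to [EPS, 1] before the logarithm
EPS = 1e-7


def relu6(x):
    """min(max(0, x), 6), elementwise."""
    return np.clip(x, 0.0, 6.0)


def hard_swish(x):
    """x · ReLU6(x + 3) / 6 — the piecewise-linear approximation of Swish."""
    x = np.asarray(x, dtype=float)
    return x * relu6(x + 3.0) / 6.0


def beta_from_counts(class_counts) -> np.ndarray:
    """Inverse-frequency class weights N/(C·n_j), normalized to mean 1."""
    n = np.asarray(class_counts, dtype=float)
    if np.any(n <= 0):
        raise ValueError("every class needs at least one training sample")
    beta = n.sum() / (len(n) * n)
    return beta / beta.mean()


@dataclass
class FocalLossConfig:
    """Focusing parameter α, per-class weights β, and the reduction mode."""

    alpha: float = 2.0
    beta: np.ndarray | None = None  # None means uniform weights
    reduction: str = "mean"

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
            if np.any(self.beta <= 0):
                raise ValueError("all beta_j must be positive")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")

    def resolved_beta(self, num_classes: int) -> np.ndarray:
        if self.beta is None:
            return np.ones(num_classes)
        if len(self.beta) != num_classes:
            raise ValueError(f"beta has length {len(self.beta)}, expected {num_classes}")
        return self.beta


def _validate_batch(probs: np.ndarray, onehot: np.ndarray) -> None:
    if probs.shape != onehot.shape:
        raise ValueError(f"probs {probs.shape} and labels {onehot.shape} disagree")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("each probability row must sum to 1")
    if not np.all(onehot.sum(axis=1) == 1):
        raise ValueError("labels must be one-hot")


def focal_loss(probs: np.ndarray, onehot: np.ndarray, cfg: FocalLossConfig = FocalLossConfig()) -> float:
    """Focal loss of an N×C probability batch against one-hot labels."""
    probs = np.asarray(probs, dtype=float)
    onehot = np.asarray(onehot)
    _validate_batch(probs, onehot)
    beta = cfg.resolved_beta(probs.shape[1])
    p_true = np.clip((probs * onehot).sum(axis=1), EPS, 1.0)
    b_true = (beta[None, :] * onehot).sum(axis=1)
    per_sample = -b_true * (1.0 - p_true) ** cfg.alpha * np.log(p_true)
    return float(per_sample.mean() if cfg.reduction == "mean" else per_sample.sum())


def focal_loss_graph(probs: Tensor, onehot: np.ndarray,
                     cfg: FocalLossConfig = FocalLossConfig()) -> Tensor:
    """Differentiable focal loss for training, on a probability Tensor."""
    beta = cfg.resolved_beta(probs.shape[1])
    p_true = (probs * Tensor(onehot)).sum(axis=1).clip_min(EPS)
    b_true = (beta[None, :] * onehot).sum(axis=1)
    focus = (1.0 - p_true).pow_const(cfg.alpha) if cfg.alpha != 0 else Tensor(np.ones(probs.shape[0]))
    per_sample = -(Tensor(b_true) * focus * p_true.log())
    return per_sample.mean() if cfg.reduction == "mean" else per_sample.sum()
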