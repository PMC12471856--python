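"""Layer objects holding trainable parameters on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batch_norm, conv2d, max_pool2d

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Dense", "MaxPool2d", "Dropout"]


class Module:
    """Minimal container: recursively collects parameters and train/eval state."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            params.extend(_collect(value))
        return params

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and batch-norm statistics."""
        out: dict[str, np.ndarray] = {}
        _walk_state(self, "", out)
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        missing = set(own) ^ set(arrays)
        if missing:
            raise ValueError(f"checkpoint mismatch for keys: {sorted(missing)[:5]}")
        for name, arr in own.items():
            arr[...] = arrays[name]


def _collect(value) -> list[Tensor]:
    # a parameter is a requires-grad *leaf*; graph tensors cached on a module
    # (activations, logits) have parents and are not trainable state
    if isinstance(value, Tensor) and value.requires_grad and not value._parents:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _walk_state(obj, prefix: str, out: dict[str, np.ndarray]) -> None:
    if isinstance(obj, Tensor):
        if obj.requires_grad and not obj._parents:
            out[prefix] = obj.data
        return
    if isinstance(obj, Module):
        for name, value in vars(obj).items():
            _walk_state(value, f"{prefix}.{name}" if prefix else name, out)
        if isinstance(obj, BatchNorm2d):
            out[f"{prefix}.running_mean"] = obj.running_mean
            out[f"{prefix}.running_var"] = obj.running_var
            out[f"{prefix}.n_updates"] = obj.n_updates
        return
    if isinstance(obj, (list, tuple)):
        for i, value in enumerate(obj):
            _walk_state(value, f"{prefix}[{i}]", out)


class Conv2d(Module):
    """Convolution with He-uniform initialized weights; bias optional (off when
    the layer is followed by batch normalization)."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: int | tuple[int, int] = 0, bias: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = cin * kernel * kernel
        limit = np.sqrt(6.0 / fan_in)
        self.weight = Tensor(rng.uniform(-limit, limit, (cout, cin, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Batch normalization whose running statistics are exponential moving
    averages with bias correction, so evaluation-mode behaviour is sensible
    even after very few training steps."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.zeros(channels, dtype=np.float32)
        self.n_updates = np.zeros(1, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            stats: dict = {}
            out = batch_norm(x, self.gamma, self.beta, True, eps=self.eps, stats_out=stats)
            m = self.momentum
            self.running_mean *= m
            self.running_mean += (1.0 - m) * stats["mean"]
            self.running_var *= m
            self.running_var += (1.0 - m) * stats["var"]
            self.n_updates += 1
            return out
        t = float(self.n_updates[0])
        if t == 0:  # never trained: normalize as identity moments
            mean = np.zeros_like(self.running_mean)
            var = np.ones_like(self.running_var)
        else:
            corr = 1.0 - self.momentum**t
            mean = self.running_mean / corr
            var = self.running_var / corr
        return batch_norm(x, self.gamma, self.beta, False, mean=mean, var=var, eps=self.eps)


class Dense(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / nin)
        self.weight = Tensor(rng.uniform(-limit, limit, (nin, nout)), requires_grad=True)
        self.bias = Tensor(np.zeros(nout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MaxPool2d(Module):
    def __init__(self, kernel: int = 2, stride: int | None = None, padding: int = 0):
        self.kernel = kernel
        self.stride = kernel if stride is None else stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class Dropout(Module):
    """Inverted dropout: identity in evaluation mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, train: bool, rng: np.random.Generator) -> Tensor:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.data.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)
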