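"""Layer and optimizer primitives on top of the autodiff core."""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .tensor import Tensor

__all__ = ["Module", "Conv1d", "MaxPool1d", "Linear", "Adam", "same_padding"]


def same_padding(kernel: int, stride: int = 1) -> Tuple[int, int]:
    """Asymmetric zero padding so that L_out = ceil(L_in / stride).

    For stride 1 this preserves length; for strided convolutions on lengths
    divisible by the stride it yields exactly L_in / stride outputs.  The
    extra sample for even kernels goes on the right.
    """
    total = max(kernel - stride, 0)
    return total // 2, total - total // 2


class Module:
    """Minimal parameter container with named sub-modules."""

    def parameters(self) -> List[Tensor]:
        out: List[Tensor] = []
        for _, p in self.named_parameters():
            out.append(p)
        return out

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{prefix}{name}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{prefix}{name}.{i}", item

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, arr in state.items():
            if own[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            own[name].data = arr.astype(own[name].data.dtype, copy=True)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv1d(Module):
    """1D convolution with He-style initialization.

    ``padding`` may be "same" (length-preserving / stride-dividing) or an
    explicit (left, right) tuple; ``activation`` is "relu" or "linear".
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: "str | Tuple[int, int]" = "same",
                 bias: bool = True, activation: str = "linear",
                 rng: Optional[np.random.Generator] = None,
                 dtype: np.dtype = np.float32):
        rng = rng if rng is not None else np.random.default_rng()
        fan_in = in_channels * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, kernel))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = same_padding(kernel, stride) if padding == "same" else tuple(padding)
        if activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        out = x.conv1d(self.weight, self.bias, stride=self.stride, padding=self.padding)
        return out.relu() if self.activation == "relu" else out


class MaxPool1d(Module):
    def __init__(self, size: int, stride: Optional[int] = None):
        self.size = size
        self.stride = size if stride is None else stride

    def forward(self, x: Tensor) -> Tensor:
        return x.maxpool1d(self.size, self.stride)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 activation: str = "linear",
                 rng: Optional[np.random.Generator] = None,
                 dtype: np.dtype = np.float32):
        rng = rng if rng is not None else np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True) if bias else None
        if activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out.relu() if self.activation == "relu" else out


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: List[Tensor], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
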