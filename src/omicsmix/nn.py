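"""Layers, activations and the Adam optimizer used by the subtyping network."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, gelu_op, normalize_op

SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit, tanh approximation.

    0.5 * x * (1 + tanh(sqrt(2/pi) * (x + 0.044715 x^3)))
    """
    return gelu_op(x)


def gelu_scalar(x) -> np.ndarray:
    """NumPy evaluation of the same tanh-approximation (no graph)."""
    x = np.asarray(x, dtype=float)
    return 0.5 * x * (1.0 + np.tanh(SQRT_2_OVER_PI * (x + 0.044715 * x**3)))


def bce(pred: Tensor, target: float | np.ndarray) -> Tensor:
    """Mean binary cross-entropy of probabilities ``pred`` against 0/1 targets."""
    target = np.asarray(target, dtype=float)
    eps = 1e-12
    p = pred * (1.0 - 2 * eps) + eps  # clamp away from {0,1} for the logs
    loss = -(Tensor(target) * p.log() + Tensor(1.0 - target) * (1.0 - p).log())
    return loss.mean()


def mse(pred: Tensor, target: Tensor | np.ndarray) -> Tensor:
    diff = pred - Tensor.as_tensor(target)
    return (diff * diff).mean()


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    training: bool = True

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Parameter):
                        out.append(item)
                    elif isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                out.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, module has {len(params)} parameters")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.astype(np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map on the last axis; Glorot-uniform init."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        limit = math.sqrt(6.0 / (in_features + out_features))
        self.weight = Parameter(rng.uniform(-limit, limit, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return normalize_op(x, axis=-1, eps=self.eps) * self.gamma + self.beta


class BatchNorm1d(Module):
    """Batch normalisation over axis 0 with running statistics for inference.

    Batches of fewer than 2 rows fall back to the running (inference)
    statistics even in training mode, to avoid degenerate batch variance.
    """

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x: Tensor) -> Tensor:
        if self.training and x.shape[0] >= 2:
            mu = x.data.mean(axis=0)
            var = x.data.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            norm = normalize_op(x, axis=0, eps=self.eps)
        else:
            norm = (x - self.running_mean) * ((self.running_var + self.eps) ** -0.5)
        return norm * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return gelu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 0.005,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
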