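"""Neural-network building blocks on top of the autograd engine.

Layers follow the familiar Module pattern: parameters are discoverable by
name for the optimizer and for checkpointing, and batch-norm keeps running
statistics so evaluation-mode forward passes are pure functions of
(input, weights).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module", "Linear", "BatchNorm1d", "ReLU", "Sequential",
    "ResidualBlock", "l2_normalize", "logsumexp", "softmax",
]


class Module:
    """Base class: parameter discovery, state export, train/eval mode."""

    def __init__(self):
        self.training = True

    def train(self):
        self.training = True
        for child in self._children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for child in self._children():
            child.eval()
        return self

    def _children(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                state[key] = value.data.copy()
            elif isinstance(value, np.ndarray):  # buffers (running stats)
                state[key] = value.copy()
            elif isinstance(value, Module):
                state.update(value.state_dict(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.state_dict(f"{key}.{i}."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                value.data = np.array(state[key], dtype=np.float64)
            elif isinstance(value, np.ndarray):
                setattr(self, name, np.array(state[key]))
            elif isinstance(value, Module):
                value.load_state_dict(state, f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{key}.{i}.")

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        # He initialization, appropriate for the ReLU stacks used here
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, scale, (in_features, out_features)),
                             requires_grad=True)
        bound = 1.0 / np.sqrt(in_features)
        self.bias = Tensor(rng.uniform(-bound, bound, out_features),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Batch normalization with running statistics for eval mode."""

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ResidualBlock(Module):
    """x + W2 relu(BN(W1 x)); identity skip keeps gradients well-scaled."""

    def __init__(self, width: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.fc1 = Linear(width, width, rng)
        self.bn = BatchNorm1d(width)
        self.fc2 = Linear(width, width, rng)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.fc2(self.bn(self.fc1(x)).relu())


def l2_normalize(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Row-normalize to unit Euclidean norm (differentiable)."""
    norm = ((x ** 2.0).sum(axis=1, keepdims=True) + eps) ** 0.5
    return x / norm


def logsumexp(x: Tensor, axis: int) -> Tensor:
    """Numerically stable log-sum-exp; the max shift is detached, which
    leaves the gradient (a softmax) unchanged."""
    m = np.max(x.data, axis=axis, keepdims=True)
    return (x - m).exp().sum(axis=axis, keepdims=True).log() + m


def softmax(x: Tensor, axis: int) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)
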