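"""Small neural-network layer and optimizer toolkit on top of ``_autograd``."""

from __future__ import annotations

import numpy as np

from ._autograd import Parameter, Tensor, sqrt


class Module:
    """Base class: collects parameters, tracks train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self):
        self.training = True
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train()
        return self

    def eval(self):
        self.training = False
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.eval()
        return self

    def state_dict(self) -> dict:
        state = {}
        for name, value in self.__dict__.items():
            if isinstance(value, Parameter):
                state[name] = value.data.copy()
            elif isinstance(value, Module):
                state[name] = value.state_dict()
            elif isinstance(value, np.ndarray):
                state[name] = value.copy()
        return state

    def load_state_dict(self, state: dict):
        for name, value in state.items():
            current = getattr(self, name)
            if isinstance(current, Parameter):
                current.data = value.copy()
            elif isinstance(current, Module):
                current.load_state_dict(value)
            elif isinstance(current, np.ndarray):
                setattr(self, name, value.copy())


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.W = Parameter(glorot(rng, in_dim, out_dim))
        self.b = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class BatchNorm1d(Module):
    """Feature-wise batch normalization with running statistics.

    Batch statistics are used in training mode; running averages in eval
    mode, so embedding extraction is deterministic and sample-independent.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            n = x.shape[0]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            xhat = (x - mu) / sqrt(var + self.eps)
        else:
            xhat = (x - self.running_mean) * (1.0 / np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


class Adam:
    """Adam with decoupled-from-nothing L2 weight decay added to the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 5e-4, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
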