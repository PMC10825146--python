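"""Neural-network building blocks on top of :mod:`autotransop.autodiff`.

Layers follow the architecture conventions of the translation framework:
hidden blocks are fully-connected -> batch-normalization -> ELU -> dropout,
and final projection layers carry no trainable bias.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module",
    "Linear",
    "BatchNorm1d",
    "Dropout",
    "FCBlock",
    "MLP",
    "Adam",
    "SGD",
]


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def submodules(self) -> list["Module"]:
        subs: list[Module] = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                subs.append(v)
            elif isinstance(v, (list, tuple)):
                subs.extend(m for m in v if isinstance(m, Module))
            elif isinstance(v, dict):
                subs.extend(m for m in v.values() if isinstance(m, Module))
        return subs

    def train(self):
        for m in self.submodules():
            m.train()
        if hasattr(self, "training"):
            self.training = True
        return self

    def eval(self):
        for m in self.submodules():
            m.eval()
        if hasattr(self, "training"):
            self.training = False
        return self

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of all parameters and buffers."""
        out: dict[str, np.ndarray] = {}

        def walk(obj, prefix):
            for k, v in obj.__dict__.items():
                name = f"{prefix}{k}"
                if isinstance(v, Tensor):
                    out[name] = v.data
                elif isinstance(v, np.ndarray):
                    out[name] = v
                elif isinstance(v, Module):
                    walk(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{name}.{i}.")
                        elif isinstance(item, Tensor):
                            out[f"{name}.{i}"] = item.data
                elif isinstance(v, dict):
                    for kk, item in v.items():
                        if isinstance(item, Module):
                            walk(item, f"{name}.{kk}.")
                        elif isinstance(item, Tensor):
                            out[f"{name}.{kk}"] = item.data

        walk(self, "")
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]):
        current = self.state_arrays()
        for name, arr in arrays.items():
            if name not in current:
                raise KeyError(f"unknown parameter {name!r} in checkpoint")
            if current[name].shape != arr.shape:
                raise ValueError(f"shape mismatch for {name!r}")
            current[name][...] = arr
        return self


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        scale = 1.0 / np.sqrt(n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None
        self.n_in, self.n_out = n_in, n_out

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class BatchNorm1d(Module):
    """Batch normalization with running statistics frozen at evaluation."""

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n), requires_grad=True)
        self.beta = Tensor(np.zeros(n), requires_grad=True)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            if x.shape[0] < 2:
                raise ValueError("batch normalization requires batch size >= 2 in training")
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            xhat = (x - mu) / (var + self.eps) ** 0.5
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.binomial(1, keep, size=x.shape) / keep
        return x * Tensor(mask)


class FCBlock(Module):
    """One hidden block: fully-connected -> batch-norm -> ELU -> dropout."""

    def __init__(self, n_in: int, n_out: int, dropout: float, rng: np.random.Generator):
        self.fc = Linear(n_in, n_out, rng)
        self.bn = BatchNorm1d(n_out)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.drop(self.bn(self.fc(x)).elu())


class MLP(Module):
    """Stack of FCBlocks followed by a bias-free linear output layer."""

    def __init__(self, n_in: int, hidden: list[int], n_out: int,
                 dropout: float, rng: np.random.Generator, out_bias: bool = False):
        sizes = [n_in] + list(hidden)
        self.blocks = [FCBlock(a, b, dropout, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.out = Linear(sizes[-1], n_out, rng, bias=out_bias)

    def __call__(self, x: Tensor) -> Tensor:
        for blk in self.blocks:
            x = blk(x)
        return self.out(x)


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    """Plain stochastic gradient descent (flag-selectable alternative)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad
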