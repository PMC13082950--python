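"""Neural-network building blocks and the Adam optimizer on top of ``gatan.autodiff``."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv3d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Container with recursive parameter discovery (attribute order is stable)."""

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []

        def visit(name, val):
            if isinstance(val, Parameter):
                out.append((name, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(name + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    visit(f"{name}.{i}", item)

        for name, val in vars(self).items():
            visit(f"{prefix}{name}", val)
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, arr in state.items():
            if own[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            own[name].data = np.asarray(arr, dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int):
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(_kaiming(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        fan_in = c_in * kernel**3
        self.weight = Parameter(_kaiming(rng, (c_out, c_in, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class LayerNorm(Module):
    """Normalization over the trailing (channel) axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


class MLP(Module):
    """Two-layer feed-forward transform with GELU-like (tanh) nonlinearity."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.fc1(x)
        # tanh-approximate GELU
        h = h * (((h * 0.7978845608 * (1.0 + h * h * 0.044715)).tanh() + 1.0) * 0.5)
        return self.fc2(h)


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
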