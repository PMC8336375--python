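"""Neural-network layers over the autodiff engine.

Conventions follow common deep-learning practice: He-uniform
initialization for convolution and linear weights, batch-norm scale 1 /
shift 0 with running statistics tracked by exponential moving average,
and an explicit train/eval mode switch on every module.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    def __init__(self):
        self.training = True

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
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- flat state dict of numpy arrays (parameters + BN buffers) -----
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                state[key] = v.data
            elif isinstance(v, np.ndarray):
                state[key] = v
            elif isinstance(v, Module):
                state.update(v.state_dict(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.state_dict(prefix=f"{key}.{i}."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.asarray(state[key], dtype=v.data.dtype)
            elif isinstance(v, np.ndarray):
                self.__dict__[name] = np.asarray(state[key], dtype=v.dtype)
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, prefix=f"{key}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
               dtype=np.float32) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv2d(Module):
    """3x3 / 7x7 same-padding, stride-1 convolution (NHWC feature maps)."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float32):
        super().__init__()
        self.kernel = kernel
        fan_in = cin * kernel * kernel
        self.weight = Tensor(he_uniform(rng, (kernel, kernel, cin, cout), fan_in, dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mean, var = T.batchnorm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(self.running_var.dtype)
            return out
        return T.batchnorm_eval(x, self.gamma, self.beta,
                                self.running_mean, self.running_var, self.eps)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.weight = Tensor(he_uniform(rng, (fin, fout), fin, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(fout, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return T.add(T.matmul(x, self.weight), self.bias)


class ConvBNReLU(Module):
    """The Conv -> BN -> ReLU unit used throughout the backbone."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, rng, bias=False, dtype=dtype)
        self.bn = BatchNorm2d(cout, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return T.relu(self.bn(self.conv(x)))
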