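"""Neural-network layers built on the :mod:`brightstain.nn.tensor` engine.

Only the pieces the virtual-staining networks use: 2-D convolution (same or
strided), 2×2 transposed convolution for upsampling, 2×2 max-pooling, batch
normalization, rectifiers and a sequential container.  Parameters are stored
float32; initialization is Kaiming-uniform for convolutions, matching common
deep-learning-framework defaults so learning-rate choices transfer.
"""

from __future__ import annotations

import math

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Tensor] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        params = list(self._params.values())
        for m in self._modules.values():
            params.extend(m.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + name, p) for name, p in self._params.items()]
        for mname, m in self._modules.items():
            out.extend(m.named_parameters(prefix + mname + "."))
        return out

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for mname, m in self._named_modules(""):
            for bname, buf in getattr(m, "_buffers", {}).items():
                state[f"{mname}{bname}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float32).copy()
        for mname, m in self._named_modules(""):
            for bname in getattr(m, "_buffers", {}):
                key = f"{mname}{bname}"
                if key in state:
                    m._buffers[bname] = np.asarray(state[key]).copy()
                    object.__setattr__(m, bname, m._buffers[bname])

    def _named_modules(self, prefix: str):
        yield prefix, self
        for mname, m in self._modules.items():
            yield from m._named_modules(prefix + mname + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


_INIT_RNG = [np.random.default_rng(0)]


def seed_init(seed: int):
    """Seed parameter initialization (module-level, mirrors manual_seed)."""
    _INIT_RNG[0] = np.random.default_rng(seed)


def _kaiming_uniform(shape, fan_in: int) -> Tensor:
    bound = math.sqrt(1.0 / fan_in)
    data = _INIT_RNG[0].uniform(-bound, bound, size=shape).astype(np.float32)
    return Tensor(data, requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = _kaiming_uniform((out_channels, fan_in), fan_in)
        self.bias = _kaiming_uniform((out_channels,), fan_in) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        k, s, p = self.kernel_size, self.stride, self.padding
        oh = (H + 2 * p - k) // s + 1
        ow = (W + 2 * p - k) // s + 1
        cols = T.unfold(x, k, s, p)                       # (B, L, C·k·k)
        cols2 = T.reshape(cols, (B * oh * ow, C * k * k))
        out = T.matmul(cols2, T.transpose(self.weight, (1, 0)))  # (B·L, O)
        out = T.reshape(out, (B, oh, ow, self.out_channels))
        out = T.transpose(out, (0, 3, 1, 2))
        if self.bias is not None:
            out = out + T.reshape(self.bias, (1, self.out_channels, 1, 1))
        return out


class ConvTranspose2d(Module):
    """Transposed convolution with kernel 2 and stride 2 (non-overlapping)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 2,
                 stride: int = 2, bias: bool = True):
        super().__init__()
        if kernel_size != 2 or stride != 2:
            raise NotImplementedError("only kernel=2, stride=2 upconvolutions are supported")
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = _kaiming_uniform((in_channels, out_channels * 4), fan_in)
        self.bias = _kaiming_uniform((out_channels,), fan_in) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        co = self.out_channels
        xr = T.reshape(T.transpose(T.reshape(x, (B, C, H * W)), (0, 2, 1)), (B * H * W, C))
        out = T.matmul(xr, self.weight)                       # (B·H·W, co·4)
        out = T.reshape(out, (B, H, W, co, 2, 2))
        out = T.transpose(out, (0, 3, 1, 4, 2, 5))            # (B, co, H, 2, W, 2)
        out = T.reshape(out, (B, co, 2 * H, 2 * W))
        if self.bias is not None:
            out = out + T.reshape(self.bias, (1, co, 1, 1))
        return out


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 2, stride: int = 2):
        super().__init__()
        if kernel_size != 2 or stride != 2:
            raise NotImplementedError("only 2x2/stride-2 pooling is supported")

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"spatial size ({H}, {W}) not divisible by 2 for pooling")
        xr = T.reshape(x, (B, C, H // 2, 2, W // 2, 2))
        xr = T.tmax(xr, axis=5)
        xr = T.tmax(xr, axis=3)
        return xr


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self._buffers = {
            "running_mean": np.zeros(num_features, dtype=np.float32),
            "running_var": np.ones(num_features, dtype=np.float32),
        }
        object.__setattr__(self, "running_mean", self._buffers["running_mean"])
        object.__setattr__(self, "running_var", self._buffers["running_var"])

    def forward(self, x: Tensor) -> Tensor:
        C = self.num_features
        if self.training:
            mu = T.tmean(x, axis=(0, 2, 3), keepdims=True)
            var = T.tmean((x - mu) ** 2, axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            n = x.size // C
            unbiased = var.data.reshape(C) * (n / max(n - 1, 1))
            self._buffers["running_mean"][:] = (1 - m) * self._buffers["running_mean"] + m * mu.data.reshape(C)
            self._buffers["running_var"][:] = (1 - m) * self._buffers["running_var"] + m * unbiased
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, C, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, C, 1, 1))
        inv = (var + np.float32(self.eps)) ** -0.5
        xhat = (x - mu) * inv
        w = T.reshape(self.weight, (1, C, 1, 1))
        b = T.reshape(self.bias, (1, C, 1, 1))
        return xhat * w + b


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.2):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x: Tensor) -> Tensor:
        return T.leaky_relu(x, self.negative_slope)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)
        self._order = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self._order:
            x = m(x)
        return x


def count_parameters(module: Module) -> int:
    """Total number of learnable scalars (weights, biases, norm affine terms)."""
    return int(sum(p.size for p in module.parameters()))
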