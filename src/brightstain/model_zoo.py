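"""The virtual-staining networks: U-Net generator and Wasserstein patch critic.

Generator: a 6-level U-Net mapping the 3-plane brightfield z-stack to the
5 fluorescent channels.  Each block is convs (kernel 3, stride 1, "same"
padding) each followed by ReLU then batch normalization; 2×2 max-pooling
between encoder blocks; 2×2 stride-2 transposed convolutions and skip
concatenations on the decoder; a final convolution with no activation or
normalization.  Filter counts double per level, 32 → 1024, which with two
convolutions per block gives ≈31 million trainable parameters.

Critic: a conditional patch critic taking the 8-channel concatenation of
brightfield and (real or generated) fluorescent stacks, three stride-2
kernel-4 convolutions ending at 64 filters, LeakyReLU activations, no
normalization layers (standard practice under a gradient penalty), and a
1×1 projection producing a spatial score map.  The scalar critic score is
the mean of the map; WGAN scores are unbounded, so there is no sigmoid.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn import tensor as T


@dataclass
class GeneratorConfig:
    in_channels: int = 3
    out_channels: int = 5
    levels: int = 6
    base_filters: int = 32
    convs_per_block: int = 2
    final_kernel: int = 1

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if self.base_filters < 1 or self.convs_per_block < 1:
            raise ValueError("base_filters and convs_per_block must be positive")

    @property
    def filters(self) -> list[int]:
        return [self.base_filters * 2 ** i for i in range(self.levels)]

    @property
    def size_divisor(self) -> int:
        return 2 ** (self.levels - 1)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CriticConfig:
    in_channels: int = 8
    n_layers: int = 3
    final_filters: int = 64
    conv_kernel: int = 4
    conv_stride: int = 2
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.final_filters % 2 ** (self.n_layers - 1):
            raise ValueError("final_filters must be divisible by 2^(n_layers-1)")

    @property
    def filters(self) -> list[int]:
        return [self.final_filters // 2 ** (self.n_layers - 1 - i) for i in range(self.n_layers)]

    def to_dict(self) -> dict:
        return asdict(self)


class _ConvBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, n_convs: int):
        super().__init__()
        layers = []
        c = in_ch
        for _ in range(n_convs):
            layers += [nn.Conv2d(c, out_ch, 3, stride=1, padding=1), nn.ReLU(), nn.BatchNorm2d(out_ch)]
            c = out_ch
        self.block = nn.Sequential(*layers)

    def forward(self, x):
        return self.block(x)


class UNetGenerator(nn.Module):
    def __init__(self, config: GeneratorConfig | None = None):
        super().__init__()
        self.config = config or GeneratorConfig()
        cfg = self.config
        f = cfg.filters
        c = cfg.in_channels
        for i in range(cfg.levels):
            setattr(self, f"down{i}", _ConvBlock(c, f[i], cfg.convs_per_block))
            c = f[i]
        self.pool = nn.MaxPool2d(2, 2)
        for i in range(cfg.levels - 2, -1, -1):
            setattr(self, f"up{i}", nn.ConvTranspose2d(f[i + 1], f[i], 2, 2))
            setattr(self, f"dec{i}", _ConvBlock(2 * f[i], f[i], cfg.convs_per_block))
        pad = (cfg.final_kernel - 1) // 2
        self.head = nn.Conv2d(f[0], cfg.out_channels, cfg.final_kernel, padding=pad)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        if x.ndim != 4 or x.shape[1] != cfg.in_channels:
            raise ValueError(
                f"expected input of shape (B, {cfg.in_channels}, S, S), got {x.shape}")
        h, w = x.shape[2], x.shape[3]
        d = cfg.size_divisor
        if h % d or w % d:
            raise ValueError(
                f"spatial size ({h}, {w}) must be divisible by 2^(levels-1) = {d}")
        skips = []
        for i in range(cfg.levels):
            x = getattr(self, f"down{i}")(x)
            if i < cfg.levels - 1:
                skips.append(x)
                x = self.pool(x)
        for i in range(cfg.levels - 2, -1, -1):
            x = getattr(self, f"up{i}")(x)
            x = T.concat([x, skips[i]], axis=1)
            x = getattr(self, f"dec{i}")(x)
        return self.head(x)

    def predict(self, brightfield: np.ndarray) -> np.ndarray:
        """Inference on a (3, S, S) or (B, 3, S, S) float array."""
        arr = np.asarray(brightfield, dtype=np.float32)
        squeeze = arr.ndim == 3
        if squeeze:
            arr = arr[None]
        self.eval()
        with nn.no_grad():
            out = self.forward(Tensor(arr)).data
        return out[0] if squeeze else out


class PatchCritic(nn.Module):
    """Conditional critic scoring local patches of (brightfield, fluorescent) pairs."""

    def __init__(self, config: CriticConfig | None = None):
        super().__init__()
        self.config = config or CriticConfig()
        cfg = self.config
        layers = []
        c = cfg.in_channels
        pad = (cfg.conv_kernel - 1) // 2  # = 1 for kernel 4: halves size under stride 2
        for f_out in cfg.filters:
            layers += [nn.Conv2d(c, f_out, cfg.conv_kernel, stride=cfg.conv_stride, padding=pad),
                       nn.LeakyReLU(cfg.leaky_slope)]
            c = f_out
        layers.append(nn.Conv2d(c, 1, 1))  # per-patch score projection
        self.net = nn.Sequential(*layers)

    def forward(self, brightfield: Tensor, fluorescent: Tensor) -> Tensor:
        """Spatial score map for the concatenated 8-channel input."""
        x = T.concat([brightfield, fluorescent], axis=1)
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"critic expects {self.config.in_channels} concatenated channels, got {x.shape[1]}")
        return self.net(x)

    def score(self, brightfield: Tensor, fluorescent: Tensor) -> Tensor:
        """Scalar critic value: mean of the patch score map over the batch."""
        return self.forward(brightfield, fluorescent).mean()


def build_generator(config: GeneratorConfig | None = None, seed: int | None = None) -> UNetGenerator:
    if seed is not None:
        nn.seed_init(seed)
    return UNetGenerator(config)


def build_critic(config: CriticConfig | None = None, seed: int | None = None) -> PatchCritic:
    if seed is not None:
        nn.seed_init(seed)
    return PatchCritic(config)


def count_trainable_parameters(network: nn.Module) -> int:
    return nn.count_parameters(network)


def save_checkpoint(path, state: dict, config: GeneratorConfig | CriticConfig,
                    extra: dict | None = None):
    """Serialize weights (.npz) with the architecture config echoed alongside."""
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.to_dict(), "kind": type(config).__name__,
            "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path):
    """Returns (network, state, extra) rebuilt from a checkpoint file."""
    import json

    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    if meta["kind"] == "GeneratorConfig":
        net = UNetGenerator(GeneratorConfig(**meta["config"]))
    else:
        net = PatchCritic(CriticConfig(**meta["config"]))
    net.load_state_dict(state)
    return net, state, meta.get("extra", {})
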