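"""Neural-network modules built on the numpy autograd engine."""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, concat

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "ConvBNReLU",
    "NestedUBlock",
    "DilatedUBlock",
    "InteractiveCrossAttention",
    "AttentionGate",
    "RecurrentResidualBlock",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self) -> None:
        self.training = True

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # buffers (batch-norm running stats) are serialized along with parameters
    def named_buffers(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, np.ndarray):
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_buffers(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer.{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, arr in state.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unexpected parameter {name!r}")
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = arr.astype(np.float32).copy()
            elif kind == "buffer":
                obj = self
                *path, leaf = name.split(".")
                for part in path:
                    obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
                setattr(obj, leaf, arr.copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int = 3, dilation: int = 1):
        super().__init__()
        self.dilation = dilation
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_he_init(rng, (kernel, kernel, in_ch, out_ch), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, dilation=self.dilation)


class ConvTranspose2x2(Module):
    """2x2, stride-2 transposed convolution: exact x2 spatial upsampling."""

    def __init__(self, rng, in_ch: int, out_ch: int):
        super().__init__()
        self.weight = Tensor(_he_init(rng, (2, 2, in_ch, out_ch), in_ch * 4), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2x2(self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(n_ch, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)

    def forward(self, x: Tensor, relu: bool = False) -> Tensor:
        if self.training:
            out, mu, var = x.batchnorm(self.gamma, self.beta, eps=self.eps, relu=relu)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
            return out
        scale = (self.gamma.data / np.sqrt(self.running_var + self.eps)).astype(np.float32)
        shift = (self.beta.data - self.running_mean * scale).astype(np.float32)
        out = x * Tensor(scale) + Tensor(shift)
        return out.relu() if relu else out


class ConvBNReLU(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, dilation: int = 1):
        super().__init__()
        self.conv = Conv2d(rng, in_ch, out_ch, kernel=3, dilation=dilation)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x), relu=True)


class NestedUBlock(Module):
    """Small U-Net nested inside one scale of the outer network.

    ``depth`` counts the encoder convolutions; the block pools ``depth - 2``
    times, applies a dilated bottom convolution, then decodes with skip
    concatenations back to full resolution. The input projection is added to
    the decoded output (residual form).
    """

    def __init__(self, rng, depth: int, in_ch: int, mid_ch: int, out_ch: int):
        super().__init__()
        if depth < 2:
            raise ValueError("inner depth must be >= 2")
        self.depth = depth
        self.conv_in = ConvBNReLU(rng, in_ch, out_ch)
        self.encoders = [ConvBNReLU(rng, out_ch if i == 0 else mid_ch, mid_ch) for i in range(depth - 1)]
        self.bottom = ConvBNReLU(rng, mid_ch, mid_ch, dilation=2)
        self.decoders = [
            ConvBNReLU(rng, 2 * mid_ch, mid_ch if i < depth - 2 else out_ch)
            for i in range(depth - 1)
        ]

    @property
    def n_pools(self) -> int:
        return self.depth - 2

    def forward(self, x: Tensor) -> Tensor:
        hin = self.conv_in(x)
        skips = []
        h = hin
        for i, enc in enumerate(self.encoders):
            h = enc(h)
            skips.append(h)
            if i < len(self.encoders) - 1:
                h = h.maxpool2x2()
        h = self.bottom(h)
        for i, dec in enumerate(self.decoders):
            skip = skips[-(i + 1)]
            h = dec(concat([h, skip]))
            if i < len(self.decoders) - 1:
                h = h.upsample_nearest(2)
        return h + hin


class DilatedUBlock(Module):
    """Resolution-preserving variant used at the bottom scales.

    A series of convolutions with increasing dilation rates replaces pooling,
    so the receptive field grows while the feature map size stays fixed.
    """

    def __init__(self, rng, in_ch: int, mid_ch: int, out_ch: int, dilation_rates=(1, 2, 4, 8)):
        super().__init__()
        rates = list(dilation_rates)
        if len(rates) < 2:
            raise ValueError("need at least 2 dilation rates")
        self.conv_in = ConvBNReLU(rng, in_ch, out_ch)
        self.encoders = [
            ConvBNReLU(rng, out_ch if i == 0 else mid_ch, mid_ch, dilation=r)
            for i, r in enumerate(rates[:-1])
        ]
        self.bottom = ConvBNReLU(rng, mid_ch, mid_ch, dilation=rates[-1])
        self.decoders = [
            ConvBNReLU(rng, 2 * mid_ch, mid_ch if i < len(rates) - 2 else out_ch, dilation=r)
            for i, r in enumerate(reversed(rates[:-1]))
        ]

    def forward(self, x: Tensor) -> Tensor:
        hin = self.conv_in(x)
        skips = []
        h = hin
        for enc in self.encoders:
            h = enc(h)
            skips.append(h)
        h = self.bottom(h)
        for i, dec in enumerate(self.decoders):
            h = dec(concat([h, skips[-(i + 1)]]))
        return h + hin


class InteractiveCrossAttention(Module):
    """Fusion of a low-level encoder feature with a high-level decoder feature.

    Compact variant: (1) cross-channel attention — channel weights from the
    globally pooled high-level feature gate the low-level feature; (2)
    interactive-cross spatial attention — a spatial map derived from each
    stream (channel mean + max, 3x3 conv, sigmoid) gates the *other* stream.
    The two gated streams are concatenated, so the output has 2 x n_ch
    channels. Exact attention arithmetic beyond this structure is a documented
    implementation choice.
    """

    def __init__(self, rng, n_ch: int, reduction: int = 2):
        super().__init__()
        hidden = max(n_ch // reduction, 1)
        self.fc1 = Conv2d(rng, n_ch, hidden, kernel=1)
        self.fc2 = Conv2d(rng, hidden, n_ch, kernel=1)
        self.spatial_low = Conv2d(rng, 2, 1, kernel=3)
        self.spatial_high = Conv2d(rng, 2, 1, kernel=3)

    def _spatial_map(self, conv: Conv2d, f: Tensor) -> Tensor:
        pooled = concat([f.mean(axis=-1, keepdims=True), f.channel_max()])
        return conv(pooled).sigmoid()

    def forward(self, f_low: Tensor, f_high: Tensor) -> Tensor:
        gap = f_high.mean(axis=(1, 2), keepdims=True)
        ch_weights = self.fc2(self.fc1(gap).relu()).sigmoid()
        f_ca = f_low * ch_weights
        s_low = self._spatial_map(self.spatial_low, f_ca)
        s_high = self._spatial_map(self.spatial_high, f_high)
        return concat([f_ca * s_high, f_high * s_low])


class AttentionGate(Module):
    """Additive attention gate on a skip connection (gating by the decoder)."""

    def __init__(self, rng, skip_ch: int, gate_ch: int, inter_ch: int | None = None):
        super().__init__()
        inter_ch = inter_ch or max(skip_ch // 2, 1)
        self.w_skip = Conv2d(rng, skip_ch, inter_ch, kernel=1)
        self.w_gate = Conv2d(rng, gate_ch, inter_ch, kernel=1)
        self.psi = Conv2d(rng, inter_ch, 1, kernel=1)

    def forward(self, skip: Tensor, gate: Tensor) -> Tensor:
        att = self.psi((self.w_skip(skip) + self.w_gate(gate)).relu()).sigmoid()
        return skip * att


class RecurrentResidualBlock(Module):
    """Two stacked recurrent convolution units with a residual 1x1 projection."""

    def __init__(self, rng, in_ch: int, out_ch: int, t: int = 2):
        super().__init__()
        self.t = t
        self.project = Conv2d(rng, in_ch, out_ch, kernel=1)
        self.rc1 = ConvBNReLU(rng, out_ch, out_ch)
        self.rc2 = ConvBNReLU(rng, out_ch, out_ch)

    def _recur(self, unit: ConvBNReLU, x: Tensor) -> Tensor:
        h = unit(x)
        for _ in range(self.t - 1):
            h = unit(x + h)
        return h

    def forward(self, x: Tensor) -> Tensor:
        x1 = self.project(x)
        return x1 + self._recur(self.rc2, self._recur(self.rc1, x1))
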