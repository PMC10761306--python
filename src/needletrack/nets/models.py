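"""Segmentation network variants.

All four variants share the same contract: input (N, H, W, 1) in [0, 1],
output a fused per-pixel probability map of the same spatial size plus a
(possibly empty) list of side-output probability maps. The nested-U variant
("uiu") supervises every side output; the three reference variants emit a
single map.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autograd import Tensor, concat
from .layers import (
    AttentionGate,
    Conv2d,
    ConvBNReLU,
    ConvTranspose2x2,
    DilatedUBlock,
    InteractiveCrossAttention,
    Module,
    NestedUBlock,
    RecurrentResidualBlock,
)

__all__ = ["NetworkSpec", "build_network", "UIUNet", "UNet", "AttentionUNet", "R2UNet"]

VARIANTS = ("uiu", "unet", "attention_unet", "r2u")


@dataclasses.dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters shared by all variants.

    ``inner_depths`` gives the nested-block depth per encoder scale (one
    entry per scale); the bottom two scales use dilated blocks and ignore
    their entries. Only the "uiu" variant uses ``inner_depths`` and
    ``dilation_rates``.
    """

    variant: str = "uiu"
    n_scales: int = 4
    inner_depths: tuple[int, ...] = (4, 3, 2, 2)
    base_channels: int = 8
    dilation_rates: tuple[int, ...] = (1, 2, 4, 8)
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.n_scales < 3:
            raise ValueError("n_scales must be >= 3")
        if len(self.inner_depths) != self.n_scales:
            raise ValueError(
                f"inner_depths must have one entry per scale ({self.n_scales}), "
                f"got {len(self.inner_depths)}"
            )
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if any(d < 2 for d in self.inner_depths[: self.n_scales - 2]):
            raise ValueError("inner depths of nested-block scales must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inner_depths"] = list(d["inner_depths"])
        d["dilation_rates"] = list(d["dilation_rates"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        for key in ("inner_depths", "dilation_rates"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class _SizeCheckedModule(Module):
    size_divisor: int = 1

    def check_input(self, x: Tensor) -> None:
        h, w = x.shape[1], x.shape[2]
        d = self.size_divisor
        if h % d or w % d or h < d or w < d:
            min_h = max(d, ((h + d - 1) // d) * d)
            min_w = max(d, ((w + d - 1) // d) * d)
            raise ValueError(
                f"input {h}x{w} incompatible with this architecture: spatial dims must be "
                f"multiples of {d}; minimum admissible size here is {min_h}x{min_w}"
            )


class UIUNet(_SizeCheckedModule):
    """Nested-U network: small U-blocks per scale, dilated bottom scales,
    interactive-cross attention fusion instead of plain skips, and deep
    supervision with side outputs fused into the final map."""

    loss = "multi_bce"

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__()
        s = spec.n_scales
        base = spec.base_channels
        ch = [base * 2 ** min(i, 2) for i in range(s)]
        mid = [max(c // 2, 1) for c in ch]
        self.spec = spec

        def make_block(scale: int, in_ch: int, out_ch: int) -> Module:
            if scale >= s - 2:  # bottom two scales keep resolution, dilate instead
                return DilatedUBlock(rng, in_ch, max(out_ch // 2, 1), out_ch, spec.dilation_rates)
            return NestedUBlock(rng, spec.inner_depths[scale], in_ch, mid[scale], out_ch)

        self.encoders = [
            make_block(i, spec.in_channels if i == 0 else ch[i - 1], ch[i]) for i in range(s)
        ]
        self.upsamplers = [ConvTranspose2x2(rng, ch[i + 1], ch[i]) for i in range(s - 1)]
        self.fusions = [InteractiveCrossAttention(rng, ch[i]) for i in range(s - 1)]
        self.decoders = [make_block(i, 2 * ch[i], ch[i]) for i in range(s - 1)]
        self.side_convs = [Conv2d(rng, ch[i], 1, kernel=3) for i in range(s - 1)]
        self.side_bottom = Conv2d(rng, ch[s - 1], 1, kernel=3)
        self.fuse_conv = Conv2d(rng, s, 1, kernel=1)

        inner_pools = [
            max(spec.inner_depths[i] - 2, 0) if i < s - 2 else 0 for i in range(s)
        ]
        self.size_divisor = 2 ** max(
            s - 1, max(i + p for i, p in enumerate(inner_pools))
        )

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        self.check_input(x)
        s = self.spec.n_scales
        enc_feats = []
        h = x
        for i, enc in enumerate(self.encoders):
            h = enc(h)
            enc_feats.append(h)
            if i < s - 1:
                h = h.maxpool2x2()

        side_logits = [None] * s
        side_logits[s - 1] = self.side_bottom(enc_feats[s - 1])
        h = enc_feats[s - 1]
        for i in range(s - 2, -1, -1):
            up = self.upsamplers[i](h)
            fused_feat = self.fusions[i](enc_feats[i], up)
            h = self.decoders[i](fused_feat)
            side_logits[i] = self.side_convs[i](h)

        full_logits = [
            sl if i == 0 else sl.upsample_nearest(2**i) for i, sl in enumerate(side_logits)
        ]
        fused = self.fuse_conv(concat(full_logits)).sigmoid()
        sides = [sl.sigmoid() for sl in full_logits]
        return fused, sides


class _EncoderDecoderNet(_SizeCheckedModule):
    """Shared encoder-decoder scaffold for the three reference variants."""

    loss = "bce"

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__()
        s = spec.n_scales
        ch = [spec.base_channels * 2**i for i in range(s)]
        self.spec = spec
        self.ch = ch
        self.encoders = [
            self.make_block(rng, spec.in_channels if i == 0 else ch[i - 1], ch[i])
            for i in range(s)
        ]
        self.upsamplers = [ConvTranspose2x2(rng, ch[i + 1], ch[i]) for i in range(s - 1)]
        self.decoders = [self.make_block(rng, 2 * ch[i], ch[i]) for i in range(s - 1)]
        self.out_conv = Conv2d(rng, ch[0], 1, kernel=1)
        self.size_divisor = 2 ** (s - 1)

    def make_block(self, rng, in_ch: int, out_ch: int) -> Module:
        raise NotImplementedError

    def fuse_skip(self, i: int, skip: Tensor, up: Tensor) -> Tensor:
        return concat([skip, up])

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        self.check_input(x)
        s = self.spec.n_scales
        enc_feats = []
        h = x
        for i, enc in enumerate(self.encoders):
            h = enc(h)
            enc_feats.append(h)
            if i < s - 1:
                h = h.maxpool2x2()
        h = enc_feats[s - 1]
        for i in range(s - 2, -1, -1):
            up = self.upsamplers[i](h)
            h = self.decoders[i](self.fuse_skip(i, enc_feats[i], up))
        return self.out_conv(h).sigmoid(), []


class _DoubleConv(Module):
    def __init__(self, rng, in_ch: int, out_ch: int):
        super().__init__()
        self.c1 = ConvBNReLU(rng, in_ch, out_ch)
        self.c2 = ConvBNReLU(rng, out_ch, out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x))


class UNet(_EncoderDecoderNet):
    def make_block(self, rng, in_ch: int, out_ch: int) -> Module:
        return _DoubleConv(rng, in_ch, out_ch)


class AttentionUNet(_EncoderDecoderNet):
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__(spec, rng)
        self.gates = [AttentionGate(rng, self.ch[i], self.ch[i]) for i in range(spec.n_scales - 1)]

    def make_block(self, rng, in_ch: int, out_ch: int) -> Module:
        return _DoubleConv(rng, in_ch, out_ch)

    def fuse_skip(self, i: int, skip: Tensor, up: Tensor) -> Tensor:
        return concat([self.gates[i](skip, up), up])


class R2UNet(_EncoderDecoderNet):
    def make_block(self, rng, in_ch: int, out_ch: int) -> Module:
        return RecurrentResidualBlock(rng, in_ch, out_ch, t=2)


def build_network(spec: NetworkSpec, seed: int = 0) -> _SizeCheckedModule:
    """Instantiate a network variant with seeded weight initialization."""
    rng = np.random.default_rng(seed)
    cls = {"uiu": UIUNet, "unet": UNet, "attention_unet": AttentionUNet, "r2u": R2UNet}[
        spec.variant
    ]
    return cls(spec, rng)
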