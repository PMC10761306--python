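"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations the segmentation networks need are provided: broadcast
arithmetic, relu/sigmoid/log, 2-D convolution (stride 1, arbitrary dilation,
'same' padding), 2x2/stride-2 transposed convolution, 2x2 max pooling,
nearest-neighbor upsampling, channel concatenation, axis means and channel
max. Everything runs in float32.

This exists because no GPU deep-learning framework is available in the
target runtime; the engine is deliberately small and the layers above it are
gradient-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
__all__ = ["Tensor", "concat", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if (_grad_enabled and self.requires_grad) else ()
        self._backward = _backward if self._parents else None

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs are deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:  # free intermediate grads eagerly? keep: params need them
                node._backward = None

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other), _backward=None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw if out._parents else None
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw if out._parents else None
        return out

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bw(g):
            self._accum(-g)

        out._backward = bw if out._parents else None
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    __radd__ = __add__
    __rmul__ = __mul__

    def pow(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = bw if out._parents else None
        return out

    def reciprocal_sqrt(self, eps: float = 1e-5):
        """1 / sqrt(x + eps), used by batch normalization."""
        inv = 1.0 / np.sqrt(self.data + eps)
        out = Tensor(inv, _parents=(self,))

        def bw(g):
            self._accum(g * (-0.5) * inv / (self.data + eps))

        out._backward = bw if out._parents else None
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))

        def bw(g):
            self._accum(g * mask)

        out._backward = bw if out._parents else None
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out = Tensor(y, _parents=(self,))

        def bw(g):
            self._accum(g * y * (1.0 - y))

        out._backward = bw if out._parents else None
        return out

    def log(self, eps: float = 1e-7):
        clipped = np.clip(self.data, eps, None)
        out = Tensor(np.log(clipped), _parents=(self,))

        def bw(g):
            self._accum(g / clipped)

        out._backward = bw if out._parents else None
        return out

    # -- reductions and shape ops -----------------------------------------

    def mean(self, axis=None, keepdims: bool = False):
        out_data = self.data.mean(axis=axis, keepdims=keepdims)
        n = self.data.size / max(out_data.size, 1)
        out = Tensor(out_data, _parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape) / n)

        out._backward = bw if out._parents else None
        return out

    def channel_max(self):
        """Max over the channel axis (last axis, NHWC), keepdims."""
        m = self.data.max(axis=-1, keepdims=True)
        out = Tensor(m, _parents=(self,))

        def bw(g):
            mask = self.data == m
            count = mask.sum(axis=-1, keepdims=True)
            self._accum(g * mask / count)

        out._backward = bw if out._parents else None
        return out

    def batchnorm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5, relu: bool = False):
        """Fused batch normalization over (N, H, W) per channel, optional ReLU.

        A single primitive (instead of a composition of means and multiplies)
        because normalization follows every convolution and would otherwise
        dominate the elementwise memory traffic. Returns (out, batch_mean,
        batch_var) so the caller can maintain running statistics.
        """
        x = self.data
        axes = tuple(range(x.ndim - 1))
        n = x.size // x.shape[-1]
        c = x.shape[-1]
        mu = x.mean(axis=axes)
        xc = x - mu
        xc2 = xc.reshape(-1, c)
        var = np.einsum("nc,nc->c", xc2, xc2) / n
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv_std
        y = xhat * gamma.data + beta.data
        if relu:
            mask = y > 0
            y = y * mask
        out = Tensor(y, _parents=(self, gamma, beta))

        def bw(g):
            if relu:
                g = g * mask
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            gxhat_sum = np.einsum("nc,nc->c", g.reshape(-1, c), xhat.reshape(-1, c))
            if gamma.requires_grad:
                gamma._accum(gxhat_sum)
            if self.requires_grad:
                gx = (gamma.data * inv_std) * (
                    g - g.mean(axis=axes) - xhat * (gxhat_sum / n)
                )
                self._accum(gx.astype(np.float32))

        out._backward = bw if out._parents else None
        return out, mu, var

    # -- spatial ops (all NHWC: channels-last keeps the per-tap slice copies
    # contiguous, which is what makes convolution fast without a C extension)

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None, dilation: int = 1):
        """'Same'-padded stride-1 2-D convolution (cross-correlation).

        Input (N, H, W, C), weight (kh, kw, C, Cout); padding keeps H, W.
        Computed as a sum over kernel taps of (N*H*W, C) @ (C, Cout) matmuls
        on shifted views, avoiding any im2col gather.
        """
        x, w = self.data, weight.data
        n, h, wd, c = x.shape
        kh, kw, ci, co = w.shape
        assert ci == c, f"channel mismatch: input {c}, weight {ci}"
        ph = dilation * (kh - 1) // 2
        pw = dilation * (kw - 1) // 2
        if ph or pw:  # np.zeros + assign beats np.pad's generic path
            xp = np.zeros((n, h + 2 * ph, wd + 2 * pw, c), dtype=np.float32)
            xp[:, ph : ph + h, pw : pw + wd, :] = x
        else:
            xp = x

        taps = [(i, j) for i in range(kh) for j in range(kw)]

        def tap_slice(i: int, j: int) -> np.ndarray:
            s = xp[:, i * dilation : i * dilation + h, j * dilation : j * dilation + wd, :]
            return np.ascontiguousarray(s).reshape(n * h * wd, c)

        slices = [tap_slice(i, j) for i, j in taps] if _grad_enabled else None
        out_flat = np.zeros((n * h * wd, co), dtype=np.float32)
        for idx, (i, j) in enumerate(taps):
            s = slices[idx] if slices is not None else tap_slice(i, j)
            out_flat += s @ w[i, j]
        if bias is not None:
            out_flat += bias.data
        parents = (self, weight) if bias is None else (self, weight, bias)
        out = Tensor(out_flat.reshape(n, h, wd, co), _parents=parents)

        def bw(g):
            g2 = g.reshape(n * h * wd, co)
            if bias is not None and bias.requires_grad:
                bias._accum(g2.sum(axis=0))
            if weight.requires_grad:
                gw = np.empty_like(w)
                for idx in range(len(taps)):
                    gw[taps[idx]] = slices[idx].T @ g2
                weight._accum(gw)
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                for i, j in taps:
                    gxp[
                        :, i * dilation : i * dilation + h, j * dilation : j * dilation + wd, :
                    ] += (g2 @ w[i, j].T).reshape(n, h, wd, c)
                self._accum(gxp[:, ph : ph + h, pw : pw + wd, :])

        out._backward = bw if out._parents else None
        return out

    def conv_transpose2x2(self, weight: "Tensor", bias: "Tensor | None" = None):
        """Transposed convolution, kernel 2x2, stride 2 (exact x2 upsampling).

        Input (N, H, W, Cin), weight (2, 2, Cin, Cout) -> (N, 2H, 2W, Cout).
        """
        x, w = self.data, weight.data
        n, h, wd, c = x.shape
        kh, kw, ci, co = w.shape
        assert ci == c and kh == 2 and kw == 2
        x_flat = x.reshape(n * h * wd, c)
        y = np.empty((n, 2 * h, 2 * wd, co), dtype=np.float32)
        for i in range(2):
            for j in range(2):
                y[:, i::2, j::2, :] = (x_flat @ w[i, j]).reshape(n, h, wd, co)
        if bias is not None:
            y += bias.data
        parents = (self, weight) if bias is None else (self, weight, bias)
        out = Tensor(y, _parents=parents)

        def bw(g):
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 1, 2)))
            gx = np.zeros_like(x_flat) if self.requires_grad else None
            gw = np.empty_like(w) if weight.requires_grad else None
            for i in range(2):
                for j in range(2):
                    gij = np.ascontiguousarray(g[:, i::2, j::2, :]).reshape(n * h * wd, co)
                    if gx is not None:
                        gx += gij @ w[i, j].T
                    if gw is not None:
                        gw[i, j] = x_flat.T @ gij
            if gx is not None:
                self._accum(gx.reshape(x.shape))
            if gw is not None:
                weight._accum(gw)

        out._backward = bw if out._parents else None
        return out

    def maxpool2x2(self):
        n, h, w, c = self.data.shape
        assert h % 2 == 0 and w % 2 == 0, f"maxpool2x2 needs even spatial dims, got {h}x{w}"
        xr = self.data.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        out = Tensor(y, _parents=(self,))

        def bw(g):
            mask = xr == y[:, :, None, :, None, :]
            count = mask.sum(axis=(2, 4), keepdims=True)
            gx = (mask * (g[:, :, None, :, None, :] / count)).reshape(n, h, w, c)
            self._accum(gx)

        out._backward = bw if out._parents else None
        return out

    def upsample_nearest(self, factor: int = 2):
        y = self.data.repeat(factor, axis=1).repeat(factor, axis=2)
        out = Tensor(y, _parents=(self,))

        def bw(g):
            n, h, w, c = self.data.shape
            self._accum(g.reshape(n, h, factor, w, factor, c).sum(axis=(2, 4)))

        out._backward = bw if out._parents else None
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bw if out._parents else None
    return out
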