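"""Minimal 1-D CNN layers with explicit manual backpropagation.

Everything operates on arrays shaped ``(N, C, T)`` (batch, channels, time).
Each layer caches what its backward pass needs during ``forward`` and
``backward(gy)`` returns the gradient w.r.t. its input while accumulating
parameter gradients in place.  Weight tensors can be wrapped in fake
quantization (per-tensor symmetric, straight-through gradients) and carry an
optional binary mask used by unstructured pruning; masked weights receive no
gradient, so they stay zero through fine-tuning.
"""

from __future__ import annotations

from typing import Iterable, Iterator, List, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .quant import ALLOWED_BITS, fake_quantize


class Param:
    """A trainable tensor: value, accumulated gradient, optional prune mask."""

    __slots__ = ("value", "grad", "mask", "prunable", "name")

    def __init__(self, value: np.ndarray, name: str = "", prunable: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.mask: Optional[np.ndarray] = None
        self.prunable = prunable
        self.name = name

    @property
    def effective(self) -> np.ndarray:
        return self.value if self.mask is None else self.value * self.mask

    def apply_mask(self) -> None:
        if self.mask is not None:
            self.value *= self.mask


class Module:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> Iterator[Param]:
        return iter(())

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)


def unique_params(params: Iterable[Param]) -> List[Param]:
    """Deduplicate by identity; candidates of a searched layer share weights."""
    seen, out = set(), []
    for p in params:
        if id(p) not in seen:
            seen.add(id(p))
            out.append(p)
    return out


def zero_grads(params: Iterable[Param]) -> None:
    for p in unique_params(params):
        p.grad[...] = 0.0


class Identity(Module):
    def forward(self, x, train=True):
        return x

    def backward(self, gy):
        return gy


class Conv1d(Module):
    """Grouped 1-D convolution with 'same' padding and optional weight quant.

    Weight shape is ``(out, in // groups, kernel)``.  ``wbits`` selects the
    fake-quantization width applied to the weights each forward pass (32 means
    none).  The weight/bias :class:`Param` objects may be supplied so several
    wrappers (e.g. the quantization variants of one searched kernel) share one
    underlying tensor.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, groups: int = 1, bias: bool = True,
                 wbits: int = 32, rng: Optional[np.random.Generator] = None,
                 weight: Optional[Param] = None, bias_param: Optional[Param] = None,
                 name: str = "conv"):
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"{name}: groups={groups} must divide in={in_channels} and out={out_channels}")
        if kernel < 1 or stride < 1:
            raise ValueError(f"{name}: kernel and stride must be >= 1")
        if wbits not in ALLOWED_BITS:
            raise ValueError(f"{name}: wbits must be one of {ALLOWED_BITS}")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride, self.groups = kernel, stride, groups
        self.wbits = wbits
        if weight is None:
            rng = rng or np.random.default_rng(0)
            fan_in = (in_channels // groups) * kernel
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(out_channels, in_channels // groups, kernel))
            weight = Param(w, name=f"{name}.w", prunable=True)
        self.w = weight
        self.b: Optional[Param]
        if bias:
            self.b = bias_param if bias_param is not None else Param(
                np.zeros(out_channels), name=f"{name}.b")
        else:
            self.b = None
        self._cache = None

    def parameters(self):
        yield self.w
        if self.b is not None:
            yield self.b

    def _pad(self, T: int) -> tuple:
        T_out = -(-T // self.stride)  # ceil
        total = max(0, (T_out - 1) * self.stride + self.kernel - T)
        return T_out, total // 2, total - total // 2

    def forward(self, x, train=True):
        N, C, T = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        T_out, pl, pr = self._pad(T)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        # windows: (N, C, T_out, K), strided view — no copy
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride, :]
        wq = fake_quantize(self.w.effective, self.wbits)
        g = self.groups
        cg_in = self.in_channels // g
        cg_out = self.out_channels // g
        y = np.empty((N, self.out_channels, T_out))
        for gi in range(g):
            xw = win[:, gi * cg_in:(gi + 1) * cg_in]
            wg = wq[gi * cg_out:(gi + 1) * cg_out]
            y[:, gi * cg_out:(gi + 1) * cg_out] = np.einsum(
                "nctk,dck->ndt", xw, wg, optimize=True)
        if self.b is not None:
            y += self.b.effective[None, :, None]
        self._cache = (win, wq, (N, C, T), (pl, pr), T_out)
        return y

    def backward(self, gy):
        win, wq, (N, C, T), (pl, pr), T_out = self._cache
        g = self.groups
        cg_in, cg_out = C // g, self.out_channels // g
        gw = np.empty_like(self.w.value)
        gx_pad = np.zeros((N, C, T + pl + pr))
        for gi in range(g):
            sl_in = slice(gi * cg_in, (gi + 1) * cg_in)
            sl_out = slice(gi * cg_out, (gi + 1) * cg_out)
            gyg = gy[:, sl_out]
            gw[sl_out] = np.einsum("nctk,ndt->dck", win[:, sl_in], gyg, optimize=True)
            # scatter gradient back through each kernel tap (vectorized over t)
            gxw = np.einsum("ndt,dck->nctk", gyg, wq[sl_out], optimize=True)
            for k in range(self.kernel):
                gx_pad[:, sl_in, k:k + self.stride * T_out:self.stride] += gxw[..., k]
        if self.w.mask is not None:  # STE through quant, then mask
            gw *= self.w.mask
        self.w.grad += gw
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 2))
        return gx_pad[:, :, pl:pl + T] if (pl or pr) else gx_pad

    @property
    def n_weights(self) -> int:
        return self.w.value.size


class BatchNorm1d(Module):
    """Per-channel batch normalization with affine parameters."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.channels = channels
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(channels), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def parameters(self):
        yield self.gamma
        yield self.beta

    def forward(self, x, train=True):
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) / std[None, :, None]
        y = self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]
        self._cache = (xhat, std, train)
        return y

    def backward(self, gy):
        xhat, std, train = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2))
        self.beta.grad += gy.sum(axis=(0, 2))
        gxhat = gy * self.gamma.value[None, :, None]
        if not train:
            return gxhat / std[None, :, None]
        m = gy.shape[0] * gy.shape[2]
        t1 = gxhat.sum(axis=(0, 2), keepdims=True) / m
        t2 = (gxhat * xhat).sum(axis=(0, 2), keepdims=True) / m
        return (gxhat - t1 - xhat * t2) / std[None, :, None]


class ReLU(Module):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class ActQuant(Module):
    """Fake-quantize activations; straight-through (identity) gradient."""

    def __init__(self, abits: int = 32):
        if abits not in ALLOWED_BITS:
            raise ValueError(f"abits must be one of {ALLOWED_BITS}")
        self.abits = abits

    def forward(self, x, train=True):
        if self.abits >= 32:
            return x
        return fake_quantize(x, self.abits)

    def backward(self, gy):
        return gy


class LogSoftmax(Module):
    """Log-softmax over the channel axis."""

    def forward(self, x, train=True):
        m = x.max(axis=1, keepdims=True)
        z = x - m
        lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
        y = z - lse
        self._softmax = np.exp(y)
        return y

    def backward(self, gy):
        return gy - self._softmax * gy.sum(axis=1, keepdims=True)


class Sequential(Module):
    def __init__(self, modules: Sequence[Module]):
        self.modules = list(modules)

    def parameters(self):
        for m in self.modules:
            yield from m.parameters()

    def forward(self, x, train=True):
        for m in self.modules:
            x = m.forward(x, train=train)
        return x

    def backward(self, gy):
        for m in reversed(self.modules):
            gy = m.backward(gy)
        return gy


class Residual(Module):
    """A block with a skip connection: ``y = body(x) + shortcut(x)``.

    The shortcut is a pointwise projection conv when channel counts differ and
    the identity otherwise.  ``active=False`` (after skip removal) reduces the
    block to its main path; the projection parameters are dropped with it.
    """

    def __init__(self, body: Module, proj: Optional[Module] = None):
        self.body = body
        self.proj = proj
        self.active = True

    def parameters(self):
        yield from self.body.parameters()
        if self.active and self.proj is not None:
            yield from self.proj.parameters()

    def forward(self, x, train=True):
        y = self.body.forward(x, train=train)
        if not self.active:
            return y
        return y + (self.proj.forward(x, train=train) if self.proj is not None else x)

    def backward(self, gy):
        gx = self.body.backward(gy)
        if not self.active:
            return gx
        return gx + (self.proj.backward(gy) if self.proj is not None else gy)

    def remove_skip(self) -> None:
        if not self.active:
            raise RuntimeError("block has no active skip connection")
        self.active = False
        self.proj = None
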