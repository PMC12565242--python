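"""Minimal reverse-mode neural-network layers on numpy.

The package trains two small networks (a slice-classification CNN and a
vision-transformer with slice-level 3D adapters).  The layers here implement
exactly the forward/backward pairs those models need; every backward pass is
checked against finite differences in the test suite.

Conventions: arrays are float64; a module caches what its backward needs
during ``forward`` and returns the input gradient from ``backward`` while
accumulating parameter gradients on :class:`Parameter.grad`.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np
from scipy.special import erf

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "DepthwiseConv3d",
    "LayerNorm",
    "GELU",
    "ReLU",
    "Dropout",
    "MultiHeadSelfAttention",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Parameter:
    """A named tensor with an accumulated gradient and a trainable flag."""

    __slots__ = ("name", "value", "grad", "trainable")

    def __init__(self, name: str, value: np.ndarray, trainable: bool = True):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter({self.name}, shape={self.value.shape}, trainable={self.trainable})"


class Module:
    """Base class: children are discovered from instance attributes."""

    def parameters(self) -> Iterator[Parameter]:
        for attr in vars(self).values():
            if isinstance(attr, Parameter):
                yield attr
            elif isinstance(attr, Module):
                yield from attr.parameters()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def set_trainable(self, flag: bool) -> None:
        for p in self.parameters():
            p.trainable = flag


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 name: str = "linear", zero_init: bool = False):
        scale = 1.0 / math.sqrt(d_in)
        w = np.zeros((d_in, d_out)) if zero_init else rng.uniform(-scale, scale, (d_in, d_out))
        self.weight = Parameter(f"{name}.weight", w)
        self.bias = Parameter(f"{name}.bias", np.zeros(d_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._x
        self.weight.grad += np.tensordot(x, gout, axes=(tuple(range(x.ndim - 1)),) * 2)
        self.bias.grad += gout.reshape(-1, gout.shape[-1]).sum(axis=0)
        return gout @ self.weight.value.T


class Conv2d(Module):
    """2D convolution (NCHW), zero padding, implemented by kernel-offset sums."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator, padding: int = 0, name: str = "conv"):
        fan_in = c_in * kernel * kernel
        scale = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(f"{name}.weight", rng.normal(0.0, scale, (c_out, c_in, kernel, kernel)))
        self.bias = Parameter(f"{name}.bias", np.zeros(c_out))
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self._xp: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        n, c, h, w = x.shape
        self._in_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        self._xp = xp
        out = np.broadcast_to(self.bias.value[None, :, None, None],
                              (n, self.weight.value.shape[0], ho, wo)).copy()
        for di in range(k):
            for dj in range(k):
                xs = xp[:, :, di:di + ho * s:s, dj:dj + wo * s:s]
                out += np.einsum("oc,nchw->nohw", self.weight.value[:, :, di, dj], xs)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        xp = self._xp
        n, c, hp, wp = xp.shape
        ho, wo = gout.shape[2], gout.shape[3]
        gxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, :, di:di + ho * s:s, dj:dj + wo * s:s]
                self.weight.grad[:, :, di, dj] += np.einsum("nohw,nchw->oc", gout, xs)
                gxp[:, :, di:di + ho * s:s, dj:dj + wo * s:s] += np.einsum(
                    "nohw,oc->nchw", gout, self.weight.value[:, :, di, dj])
        self.bias.grad += gout.sum(axis=(0, 2, 3))
        if p:
            gxp = gxp[:, :, p:-p, p:-p]
        return gxp


class DepthwiseConv3d(Module):
    """Depth-wise 3D convolution over a (N, T, H, W, C) volume, one filter per
    channel, zero 'same' padding, stride 1.

    This is the slice-mixing primitive of the slice-level adapter: kernel
    (k_t, 1, 1) mixes only along the slice axis, (1, k_h, k_w) only within a
    slice, and the channel dimension is never mixed.
    """

    def __init__(self, channels: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator, name: str = "dwconv3d",
                 identity_init: bool = False):
        kt, kh, kw = kernel
        if kt % 2 == 0 or kh % 2 == 0 or kw % 2 == 0:
            raise ValueError(f"kernel dims must be odd, got {kernel}")
        if identity_init:
            w = np.zeros((channels, kt, kh, kw))
            w[:, kt // 2, kh // 2, kw // 2] = 1.0
        else:
            scale = math.sqrt(1.0 / (kt * kh * kw))
            w = rng.normal(0.0, scale, (channels, kt, kh, kw))
        self.weight = Parameter(f"{name}.weight", w)
        self.bias = Parameter(f"{name}.bias", np.zeros(channels))
        self.kernel = (kt, kh, kw)
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        kt, kh, kw = self.kernel
        n, t, h, w, c = x.shape
        pt, ph, pw = kt // 2, kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (pt, pt), (ph, ph), (pw, pw), (0, 0)))
        self._xp = xp
        out = np.broadcast_to(self.bias.value, x.shape).copy()
        for dt in range(kt):
            for dh in range(kh):
                for dw in range(kw):
                    out += self.weight.value[:, dt, dh, dw] * xp[:, dt:dt + t, dh:dh + h, dw:dw + w, :]
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        kt, kh, kw = self.kernel
        n, t, h, w, c = gout.shape
        pt, ph, pw = kt // 2, kh // 2, kw // 2
        xp = self._xp
        gxp = np.zeros_like(xp)
        for dt in range(kt):
            for dh in range(kh):
                for dw in range(kw):
                    xs = xp[:, dt:dt + t, dh:dh + h, dw:dw + w, :]
                    self.weight.grad[:, dt, dh, dw] += np.einsum("nthwc,nthwc->c", gout, xs)
                    gxp[:, dt:dt + t, dh:dh + h, dw:dw + w, :] += gout * self.weight.value[:, dt, dh, dw]
        self.bias.grad += gout.sum(axis=(0, 1, 2, 3))
        return gxp[:, pt:t + pt, ph:h + ph, pw:w + pw, :]


class LayerNorm(Module):
    def __init__(self, d: int, name: str = "ln", eps: float = 1e-6):
        self.gamma = Parameter(f"{name}.weight", np.ones(d))
        self.beta = Parameter(f"{name}.bias", np.zeros(d))
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        d = xhat.shape[-1]
        self.gamma.grad += (gout * xhat).reshape(-1, d).sum(axis=0)
        self.beta.grad += gout.reshape(-1, d).sum(axis=0)
        gxhat = gout * self.gamma.value
        return inv * (gxhat - gxhat.mean(axis=-1, keepdims=True)
                      - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True))


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


class GELU(Module):
    """Exact Gaussian-error linear unit, 0.5*x*(1+erf(x/sqrt(2)))."""

    def __init__(self):
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return 0.5 * x * (1.0 + erf(x * _INV_SQRT2))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._x
        cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        return gout * (cdf + x * pdf)


class ReLU(Module):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, 0.0)


class Dropout(Module):
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Standard multi-head self-attention on (B, L, d) sequences."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator, name: str = "attn"):
        if d % n_heads:
            raise ValueError(f"embed dim {d} not divisible by {n_heads} heads")
        self.d, self.n_heads, self.head_dim = d, n_heads, d // n_heads
        self.qkv = Linear(d, 3 * d, rng, name=f"{name}.qkv")
        self.proj = Linear(d, d, rng, name=f"{name}.proj")
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, l, d = x.shape
        nh, hd = self.n_heads, self.head_dim
        qkv = self.qkv.forward(x).reshape(b, l, 3, nh, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]                       # (b, nh, l, hd)
        scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(hd)
        attn = softmax(scores, axis=-1)
        ctx = attn @ v                                          # (b, nh, l, hd)
        self._cache = (q, k, v, attn, (b, l, d))
        out = ctx.transpose(0, 2, 1, 3).reshape(b, l, d)
        return self.proj.forward(out)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        q, k, v, attn, (b, l, d) = self._cache
        nh, hd = self.n_heads, self.head_dim
        gctx = self.proj.backward(gout).reshape(b, l, nh, hd).transpose(0, 2, 1, 3)
        gattn = gctx @ v.transpose(0, 1, 3, 2)
        gv = attn.transpose(0, 1, 3, 2) @ gctx
        gscores = attn * (gattn - (gattn * attn).sum(axis=-1, keepdims=True))
        gscores /= math.sqrt(hd)
        gq = gscores @ k
        gk = gscores.transpose(0, 1, 3, 2) @ q
        gqkv = np.stack([gq, gk, gv]).transpose(1, 3, 0, 2, 4).reshape(b, l, 3 * d)
        return self.qkv.backward(gqkv)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          class_weights: np.ndarray | None = None
                          ) -> tuple[float, np.ndarray]:
    """Weighted cross-entropy; returns (mean loss, d loss / d logits).

    With class weights w the loss is sum_i w[y_i] * nll_i / sum_i w[y_i]
    (the usual weighted-mean convention), so a 1:1.5 weighting scales each
    positive sample's loss term by exactly 1.5 before normalisation.
    """
    n, k = logits.shape
    p = softmax(logits, axis=-1)
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None))
    if class_weights is None:
        loss = float(nll.mean())
        glogits = p.copy()
        glogits[np.arange(n), labels] -= 1.0
        glogits /= n
    else:
        w = np.asarray(class_weights, dtype=np.float64)[labels]
        wsum = w.sum()
        loss = float((w * nll).sum() / wsum)
        glogits = p * w[:, None]
        glogits[np.arange(n), labels] -= w
        glogits /= wsum
    return loss, glogits


class Adam:
    """Adam over a parameter list; frozen parameters are never touched."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine-annealed learning rate, base_lr at epoch 0 down to 0."""
    if total_epochs <= 1:
        return base_lr
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / total_epochs))
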