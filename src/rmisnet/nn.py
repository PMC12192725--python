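"""Layers for the segmentation network, built on :mod:`rmisnet.autodiff`.

Each layer is a :class:`Module` exposing ``__call__`` (tape-recorded
forward), ``parameters()`` and two analytic accounting hooks used by the
profiler: ``param_count()`` and ``macs(in_hw)`` (closed-form
multiply-accumulate count for one forward pass at a given spatial size).
Normalisations, activations and pooling contribute zero MACs by the usual
lightweight-network convention.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .autodiff import Tensor

SQRT2 = float(np.sqrt(2.0))


# ---------------------------------------------------------------------------
# initialisers (all take an explicit Generator: full-run determinism)
# ---------------------------------------------------------------------------

def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated at +-2 std, the usual MLP-block init."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x.astype(np.float32)


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)).astype(np.float32)


# ---------------------------------------------------------------------------
# functional pieces shared with plain-array code paths
# ---------------------------------------------------------------------------

def gelu_array(x):
    """GELU(x) = x * Phi(x) evaluated through the error function."""
    x = np.asarray(x, dtype=float)
    out = x * 0.5 * (1.0 + special.erf(x / SQRT2))
    return out if out.ndim else float(out)


def gelu_t(x: Tensor) -> Tensor:
    return x * 0.5 * (1.0 + (x * (1.0 / SQRT2)).erf())


def interp_matrix(n_in: int, n_out: int, dtype=np.float64) -> np.ndarray:
    """Row-stochastic matrix performing 1-D bilinear resampling.

    Corners of input and output are aligned, so source position of output
    index ``i`` is ``i * (n_in - 1) / (n_out - 1)``; each output value is the
    two-point weighted sum with weights ``(1 - u, u)``.
    """
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_out == 1 or n_in == 1:
        m[:, 0] = 1.0
        return m
    src = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    x0 = np.minimum(np.floor(src).astype(int), n_in - 2)
    u = src - x0
    m[np.arange(n_out), x0] = 1.0 - u
    m[np.arange(n_out), x0 + 1] = u
    return m


# ---------------------------------------------------------------------------
# module base
# ---------------------------------------------------------------------------

class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def register(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value, dtype=np.float32), requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, t in self._params.items():
            yield prefix + name, t
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def train(self):
        self.training = True
        for c in self._children.values():
            c.train()
        return self

    def eval(self):
        self.training = False
        for c in self._children.values():
            c.eval()
        return self

    def param_count(self) -> int:
        return int(sum(t.data.size for t in self.parameters()))

    def zero_grad(self):
        for t in self.parameters():
            t.zero_grad()


class Conv2d(Module):
    """k x k convolution via im2col; stride/padding as configured."""

    def __init__(self, in_ch, out_ch, ksize, stride=1, pad=None, *, rng, bias=True):
        super().__init__()
        self.in_ch, self.out_ch, self.ksize = in_ch, out_ch, ksize
        self.stride = stride
        self.pad = (ksize // 2) if pad is None else pad
        fan_in = in_ch * ksize * ksize
        self.weight = self.register(
            "weight", kaiming_normal(rng, (out_ch, in_ch, ksize, ksize), fan_in)
        )
        self.bias = self.register("bias", np.zeros(out_ch)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        b = x.shape[0]
        cols, (ho, wo) = x.im2col(self.ksize, self.stride, self.pad)
        wm = self.weight.reshape(self.out_ch, self.in_ch * self.ksize**2)
        out = (wm @ cols).reshape(b, self.out_ch, ho, wo)
        if self.bias is not None:
            out = out + self.bias.reshape(1, self.out_ch, 1, 1)
        return out

    def out_hw(self, in_hw):
        h, w = in_hw
        k, s, p = self.ksize, self.stride, self.pad
        return ((h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1)

    def macs(self, in_hw) -> int:
        ho, wo = self.out_hw(in_hw)
        return self.out_ch * self.in_ch * self.ksize**2 * ho * wo


class Linear(Module):
    """Token-wise affine map (..., in) -> (..., out)."""

    def __init__(self, in_dim, out_dim, *, rng):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.weight = self.register("weight", trunc_normal(rng, (in_dim, out_dim)))
        self.bias = self.register("bias", np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def macs_per_token(self) -> int:
        return self.in_dim * self.out_dim


class DWConv2d(Module):
    """Depthwise 3x3 convolution: one kernel per channel, no mixing."""

    def __init__(self, channels, *, rng, ksize=3):
        super().__init__()
        self.channels, self.ksize = channels, ksize
        self.weight = self.register(
            "weight", kaiming_normal(rng, (channels, ksize, ksize), ksize * ksize)
        )
        self.bias = self.register("bias", np.zeros(channels))

    def __call__(self, x: Tensor) -> Tensor:
        k = self.ksize
        pad = k // 2
        h, w = x.shape[2], x.shape[3]
        xp = x.pad2d(pad)
        out = None
        for i in range(k):
            for j in range(k):
                term = xp[:, :, i : i + h, j : j + w] * self.weight[:, i, j].reshape(
                    1, self.channels, 1, 1
                )
                out = term if out is None else out + term
        return out + self.bias.reshape(1, self.channels, 1, 1)

    def macs(self, in_hw) -> int:
        h, w = in_hw
        return self.channels * self.ksize**2 * h * w


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.gamma = self.register("gamma", np.ones(channels))
        self.beta = self.register("beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        c = self.channels
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(c).astype(np.float32)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.reshape(c).astype(np.float32)
            )
            inv = (var + self.eps) ** -0.5
            xhat = xc * inv
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            xhat = (x - mu) * Tensor(inv)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LayerNorm(Module):
    """Normalisation over the trailing (embedding) dimension."""

    def __init__(self, dim, eps=1e-6):
        super().__init__()
        self.dim, self.eps = dim, eps
        self.gamma = self.register("gamma", np.ones(dim))
        self.beta = self.register("beta", np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class Adam:
    """Adam with per-step learning rate injection (cosine schedule)."""

    def __init__(self, params: list[Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
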