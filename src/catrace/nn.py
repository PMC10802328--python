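"""Minimal NumPy neural-network primitives for the voxel classifier.

Only what the classifier needs: parameter containers, 3D convolution and
stride-2 transposed convolution, layer/instance normalization, multi-head
self-attention, and a transformer MLP. Forward passes are deterministic;
dropout layers are architectural markers that act as the identity (the
package performs inference and desk-scale exercises, not training).

Weights are initialized from an explicit seeded generator so that model
construction is exactly reproducible; parameter counts are independent of
the seed.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

DTYPE = np.float32


class Module:
    """Base class: tracks parameter arrays and child modules in order."""

    def __init__(self) -> None:
        self._params: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}

    def register(self, name: str, array: np.ndarray) -> np.ndarray:
        self._params[name] = array
        return array

    def __setattr__(self, name: str, value) -> None:
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        super().__setattr__(name, value)

    def add(self, name: str, module: "Module") -> "Module":
        """Register a child under an explicit name (for module lists)."""
        self._children[name] = module
        return module

    def parameters(self) -> Iterator[np.ndarray]:
        yield from self._params.values()
        for child in self._children.values():
            yield from child.parameters()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True) -> None:
        super().__init__()
        bound = math.sqrt(6.0 / (d_in + d_out))
        self.w = self.register(
            "w", rng.uniform(-bound, bound, (d_in, d_out)).astype(DTYPE))
        self.b = self.register("b", np.zeros(d_out, DTYPE)) if bias else None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.g = self.register("g", np.ones(dim, DTYPE))
        self.b = self.register("b", np.zeros(dim, DTYPE))
        self.eps = eps

    def __call__(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(-1, keepdims=True)
        var = x.var(-1, keepdims=True)
        return (x - mu) / np.sqrt(var + self.eps) * self.g + self.b


def gelu(x: np.ndarray) -> np.ndarray:
    # Exact erf form.
    from scipy.special import erf
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def leaky_relu(x: np.ndarray, slope: float = 0.01) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention with fused QKV projection."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        n, dim = x.shape
        qkv = self.qkv(x).reshape(n, 3, self.n_heads, self.d_head)
        q, k, v = qkv[:, 0], qkv[:, 1], qkv[:, 2]  # (n, heads, d_head)
        att = np.einsum("nhd,mhd->hnm", q, k) / math.sqrt(self.d_head)
        att = softmax(att, axis=-1)
        out = np.einsum("hnm,mhd->nhd", att, v).reshape(n, dim)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm block: LN -> MHSA -> residual, LN -> MLP(GELU) -> residual."""

    def __init__(self, dim: int, n_heads: int, mlp_dim: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_dim, rng)
        self.fc2 = Linear(mlp_dim, dim, rng)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = x + self.attn(self.ln1(x))
        x = x + self.fc2(gelu(self.fc1(self.ln2(x))))
        return x


class Conv3d(Module):
    """3D convolution, 'same' padding for odd kernels, stride 1.

    Weight layout (c_out, c_in, k, k, k); bias optional (the decoder runs
    bias-free because every convolution is followed by instance
    normalization).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, bias: bool = False) -> None:
        super().__init__()
        fan_in = c_in * kernel ** 3
        std = math.sqrt(2.0 / fan_in)
        self.w = self.register(
            "w", (rng.standard_normal((c_out, c_in, kernel, kernel, kernel))
                  * std).astype(DTYPE))
        self.b = self.register("b", np.zeros(c_out, DTYPE)) if bias else None
        self.kernel = kernel

    def __call__(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        if k == 1:
            y = np.einsum("cdhw,oc->odhw", x, self.w[:, :, 0, 0, 0])
        else:
            pad = k // 2
            xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
            win = np.lib.stride_tricks.sliding_window_view(
                xp, (k, k, k), axis=(1, 2, 3))
            y = np.einsum("cdhwijk,ocijk->odhw", win, self.w, optimize=True)
        if self.b is not None:
            y = y + self.b[:, None, None, None]
        return y.astype(DTYPE)


class ConvTranspose3d(Module):
    """Stride-2, kernel-2 transposed convolution (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = c_in * 8
        std = math.sqrt(2.0 / fan_in)
        self.w = self.register(
            "w", (rng.standard_normal((c_in, c_out, 2, 2, 2)) * std).astype(DTYPE))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        y = np.einsum("cdhw,coijk->odihjwk", x, self.w, optimize=True)
        return y.reshape(y.shape[0], 2 * d, 2 * h, 2 * w).astype(DTYPE)


class InstanceNorm3d(Module):
    """Non-affine instance normalization over the spatial axes."""

    def __init__(self, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps

    def __call__(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        return ((x - mu) / np.sqrt(var + self.eps)).astype(DTYPE)


class ConvNormAct(Module):
    """Convolution -> instance norm -> LeakyReLU."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.conv = Conv3d(c_in, c_out, kernel, rng)
        self.norm = InstanceNorm3d()

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return leaky_relu(self.norm(self.conv(x)))


class ResidualBlock(Module):
    """Two 3x3x3 conv-norm-act layers with a 1x1x1 shortcut projection."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv1 = ConvNormAct(c_in, c_out, 3, rng)
        self.conv2 = Conv3d(c_out, c_out, 3, rng)
        self.norm2 = InstanceNorm3d()
        self.shortcut = Conv3d(c_in, c_out, 1, rng)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        y = self.norm2(self.conv2(self.conv1(x)))
        return leaky_relu(y + self.shortcut(x))


class Dropout(Module):
    """Architectural marker; identity at inference (no training here)."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return x
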