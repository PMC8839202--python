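"""Minimal numpy layer library with manual backpropagation.

All layers operate on float64 arrays in NCHW layout (example, channel, row,
column).  Each layer caches what it needs during :meth:`forward` and releases
gradients into ``Parameter.grad`` during :meth:`backward`; the caller drives
the graph (see :class:`multipath_unet.model.MultiPathUNet`).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter({self.name or 'unnamed'}, shape={self.value.shape})"


class Layer:
    """Base class: stateless unless a subclass declares parameters."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, *, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...],
               fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W) padded input -> (N*Ho*Wo, C*k*k) patch matrix, stride 1."""
    n = x.shape[0]
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,Ho,Wo,k,k)
    win = win.transpose(0, 2, 3, 1, 4, 5)
    return win.reshape(n * win.shape[1] * win.shape[2], -1)


class Conv2d(Layer):
    """2D convolution, stride 1, spatial-size-preserving padding.

    ``bias=False`` is used throughout the network wherever a normalization
    layer follows (the norm's shift absorbs any bias).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 name: str = "conv") -> None:
        if rng is None:
            rng = np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.pad = kernel // 2
        fan_in = in_channels * kernel * kernel
        self.weight = Parameter(
            he_uniform(rng, (out_channels, in_channels, kernel, kernel), fan_in),
            name=f"{name}.weight")
        self.bias = Parameter(np.zeros(out_channels), name=f"{name}.bias") \
            if bias else None
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        ps = [self.weight]
        if self.bias is not None:
            ps.append(self.bias)
        return ps

    def _apply(self, x: np.ndarray, w: np.ndarray,
               b: np.ndarray | None) -> np.ndarray:
        n, _, h, wd = x.shape
        f = w.shape[0]
        if h < self.kernel or wd < self.kernel:
            raise ValueError(
                f"spatial dims {h}x{wd} smaller than kernel {self.kernel}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad),
                        (self.pad, self.pad)))
        cols = _im2col(xp, self.kernel)
        y = cols @ w.reshape(f, -1).T
        if b is not None:
            y += b
        return y.reshape(n, h, wd, f).transpose(0, 3, 1, 2)

    def forward(self, x, *, training=False, rng=None):
        self._x = x
        return self._apply(x, self.weight.value,
                           None if self.bias is None else self.bias.value)

    def backward(self, dy):
        x = self._x
        n, _, h, w = x.shape
        f = self.out_channels
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(-1, f)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad),
                        (self.pad, self.pad)))
        cols = _im2col(xp, self.kernel)
        self.weight.grad += (dy_mat.T @ cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dy_mat.sum(axis=0)
        # dx = correlation of dy with the 180-degree-rotated, transposed kernel
        w_flip = self.weight.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        return self._apply(dy, w_flip, None)


class ConvTranspose2d(Layer):
    """Transposed convolution with kernel size equal to stride.

    With kernel == stride the output blocks do not overlap: every input pixel
    expands into one p-by-p patch, which is the upsampling scheme used on the
    decoder side of each pathway.
    """

    def __init__(self, in_channels: int, out_channels: int, pool: int,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 name: str = "deconv") -> None:
        if rng is None:
            rng = np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.pool = pool
        self.weight = Parameter(
            he_uniform(rng, (in_channels, out_channels, pool, pool),
                       in_channels),
            name=f"{name}.weight")
        self.bias = Parameter(np.zeros(out_channels), name=f"{name}.bias") \
            if bias else None
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        ps = [self.weight]
        if self.bias is not None:
            ps.append(self.bias)
        return ps

    def forward(self, x, *, training=False, rng=None):
        self._x = x
        n, _, h, w = x.shape
        p = self.pool
        y6 = np.einsum("ncij,cfab->nfiajb", x, self.weight.value,
                       optimize=True)
        y = y6.reshape(n, self.out_channels, h * p, w * p)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        return y

    def backward(self, dy):
        x = self._x
        n, _, h, w = x.shape
        p = self.pool
        dy6 = dy.reshape(n, self.out_channels, h, p, w, p)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        self.weight.grad += np.einsum("ncij,nfiajb->cfab", x, dy6,
                                      optimize=True)
        return np.einsum("nfiajb,cfab->ncij", dy6, self.weight.value,
                         optimize=True)


class MaxPool2d(Layer):
    """Max pooling with window == stride; requires divisible spatial dims."""

    def __init__(self, pool: int) -> None:
        self.pool = pool
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x, *, training=False, rng=None):
        n, c, h, w = x.shape
        p = self.pool
        if h % p or w % p:
            raise ValueError(f"spatial dims {h}x{w} not divisible by pool {p}")
        xr = x.reshape(n, c, h // p, p, w // p, p)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // p, w // p,
                                                    p * p)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        p = self.pool
        dxr = np.zeros((n, c, h // p, w // p, p * p))
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // p, w // p, p, p).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1) -> None:
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x, *, training=False, rng=None):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class InstanceNorm2d(Layer):
    """Per-example, per-channel spatial normalization with affine transform."""

    def __init__(self, channels: int, eps: float = 1e-5,
                 name: str = "inorm") -> None:
        self.channels = channels
        self.eps = eps
        self.gain = Parameter(np.ones(channels), name=f"{name}.gain")
        self.bias = Parameter(np.zeros(channels), name=f"{name}.bias")
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gain, self.bias]

    def forward(self, x, *, training=False, rng=None):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gain.value[None, :, None, None] * xhat \
            + self.bias.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv = self._cache
        m = xhat.shape[2] * xhat.shape[3]
        self.gain.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gain.value[None, :, None, None]
        # standard normalization backward over the spatial axes
        t1 = dxhat - dxhat.mean(axis=(2, 3), keepdims=True)
        t2 = xhat * (dxhat * xhat).sum(axis=(2, 3), keepdims=True) / m
        return inv * (t1 - t2)


class CrossChannelLayerNorm(Layer):
    """Normalization across the channel axis per example and spatial position.

    This is the bottleneck interconnect: after the pathway feature maps are
    concatenated, the mean and variance are taken over all channels at each
    pixel of each example, and an adaptive gain/bias with the spatial shape of
    a single feature map is applied (broadcast over examples and channels).
    """

    def __init__(self, height: int, width: int, eps: float = 1e-5,
                 name: str = "lnorm") -> None:
        self.eps = eps
        self.gain = Parameter(np.ones((height, width)), name=f"{name}.gain")
        self.bias = Parameter(np.zeros((height, width)), name=f"{name}.bias")
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gain, self.bias]

    def forward(self, x, *, training=False, rng=None):
        if x.shape[2:] != self.gain.value.shape:
            raise ValueError(
                f"stack spatial shape {x.shape[2:]} does not match "
                f"norm parameters {self.gain.value.shape}")
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gain.value[None, None] * xhat + self.bias.value[None, None]

    def backward(self, dy):
        xhat, inv = self._cache
        m = xhat.shape[1]
        self.gain.grad += (dy * xhat).sum(axis=(0, 1))
        self.bias.grad += dy.sum(axis=(0, 1))
        dxhat = dy * self.gain.value[None, None]
        t1 = dxhat - dxhat.mean(axis=1, keepdims=True)
        t2 = xhat * (dxhat * xhat).sum(axis=1, keepdims=True) / m
        return inv * (t1 - t2)


class SpatialDropout2d(Layer):
    """Channel-wise dropout: whole feature maps are zeroed together.

    Zeroing entire maps (rather than single pixels) promotes independence
    between feature maps; survivors are rescaled by 1/(1-rate) so the
    expected activation is unchanged.  Identity at inference time.
    """

    def __init__(self, rate: float) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self._scale_mask: np.ndarray | None = None

    def forward(self, x, *, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._scale_mask = None
            return x
        if rng is None:
            rng = np.random.default_rng(0)
        keep = rng.random((x.shape[0], x.shape[1], 1, 1)) >= self.rate
        self._scale_mask = keep / (1.0 - self.rate)
        return x * self._scale_mask

    def backward(self, dy):
        if self._scale_mask is None:
            return dy
        return dy * self._scale_mask


class Softmax(Layer):
    """Numerically stable softmax over the channel (class) axis."""

    def __init__(self) -> None:
        self._p: np.ndarray | None = None

    def forward(self, x, *, training=False, rng=None):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, dy):
        p = self._p
        return p * (dy - (dy * p).sum(axis=1, keepdims=True))


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float | None = None) -> None:
        if lr is None:
            lr = self.lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)
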