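"""Minimal NumPy deep-learning core for the residual gait classifier.

Implements exactly the layers the network needs — 2-D convolution (im2col
+ BLAS matmul), batch normalization, ReLU, global average pooling, a
linear head, sigmoid — each with an explicit backward pass, plus the
residual unit x -> activation(shortcut(x) + F(x)). Everything is plain
``float32``/``float64`` ndarrays; determinism is governed entirely by the
seed used at construction.

Conventions: activations are ``(N, C, H, W)``; each module's
``forward(x, train)`` caches what its ``backward(grad)`` needs only when
``train`` is true; gradients accumulate into ``Parameter.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Linear",
    "GlobalAvgPool",
    "Sigmoid",
    "ResidualUnit",
]


class Parameter:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    def parameters(self) -> list[Parameter]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batch-norm running statistics)."""
        return []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    N, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (H + 2 * pad - kh) // stride + 1
    ow = (W + 2 * pad - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # N, C, oh, ow, kh, kw
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(N, oh * ow, C * kh * kw), oh, ow


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    N, C, H, W = x_shape
    oh = (H + 2 * pad - kh) // stride + 1
    ow = (W + 2 * pad - kw) // stride + 1
    d = dcols.reshape(N, oh, ow, C, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += d[:, :, i, j]
    if pad:
        return dxp[:, :, pad:pad + H, pad:pad + W]
    return dxp


class Conv2d(Module):
    """2-D convolution with Kaiming fan-in initialization."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, *,
                 rng: np.random.Generator, dtype=np.float32):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels, kernel, kernel))
        self.W = Parameter(w.astype(dtype))
        self.b = Parameter(np.zeros(out_channels, dtype=dtype))
        self._cache = None

    def out_side(self, side: int) -> int:
        return (side + 2 * self.padding - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols, oh, ow = _im2col(x, self.kernel, self.kernel,
                               self.stride, self.padding)
        if train:
            self._cache = (x.shape, cols)
        wmat = self.W.data.reshape(self.out_channels, -1)
        y = cols @ wmat.T + self.b.data           # N, L, out
        N = x.shape[0]
        return np.ascontiguousarray(
            y.transpose(0, 2, 1).reshape(N, self.out_channels, oh, ow))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("Conv2d.backward called without a training forward")
        x_shape, cols = self._cache
        N, oc, oh, ow = dy.shape
        dyf = np.ascontiguousarray(
            dy.reshape(N, oc, oh * ow).transpose(0, 2, 1))   # N, L, out
        self.W.grad += np.tensordot(dyf, cols, axes=([0, 1], [0, 1])
                                    ).reshape(self.W.data.shape)
        self.b.grad += dyf.sum(axis=(0, 1))
        dcols = dyf @ self.W.data.reshape(oc, -1)
        return _col2im(dcols, x_shape, self.kernel, self.kernel,
                       self.stride, self.padding)

    def parameters(self):
        return [self.W, self.b]


class BatchNorm2d(Module):
    def __init__(self, channels: int, *, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32):
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c = x.shape[1]
        g = self.gamma.data.reshape(1, c, 1, 1)
        b = self.beta.data.reshape(1, c, 1, 1)
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            istd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(1, c, 1, 1)) * istd.reshape(1, c, 1, 1)
            self._cache = (xhat, istd)
            m = self.momentum
            # in place, so buffer references held elsewhere stay valid
            self.running_mean *= (1.0 - m)
            self.running_mean += (m * mean).astype(self.running_mean.dtype)
            self.running_var *= (1.0 - m)
            self.running_var += (m * var).astype(self.running_var.dtype)
        else:
            istd = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean.reshape(1, c, 1, 1)) \
                * istd.reshape(1, c, 1, 1)
        return g * xhat + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("BatchNorm2d.backward called without a training forward")
        xhat, istd = self._cache
        N, c, H, W = dy.shape
        m = N * H * W
        dbeta = dy.sum(axis=(0, 2, 3))
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dbeta
        self.gamma.grad += dgamma
        g = self.gamma.data.reshape(1, c, 1, 1)
        dx = (g * istd.reshape(1, c, 1, 1) / m) * (
            m * dy - dbeta.reshape(1, c, 1, 1) - xhat * dgamma.reshape(1, c, 1, 1))
        return dx

    def parameters(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator, dtype=np.float32):
        w = rng.normal(0.0, np.sqrt(2.0 / in_features),
                       size=(out_features, in_features))
        self.W = Parameter(w.astype(dtype))
        self.b = Parameter(np.zeros(out_features, dtype=dtype))
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.W.data.T + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += dy.T @ self._cache
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.data

    def parameters(self):
        return [self.W, self.b]


class GlobalAvgPool(Module):
    """Adaptive average pooling to 1x1, flattened to (N, C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (H * W),
                               (N, C, H, W)).astype(dy.dtype).copy()


class Sigmoid(Module):
    def __init__(self):
        self._out = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._out * (1.0 - self._out)


class ResidualUnit(Module):
    """x -> activation(shortcut(x) + F(x)) with a two-convolution branch.

    The branch is conv(3x3) - BN - ReLU - conv(3x3) - BN. The shortcut is
    the identity when the unit preserves shape, otherwise a strided 1x1
    projection followed by BN. ``post_activation`` applies the usual ReLU
    after the addition; disabling it exposes the raw additive identity
    x + F(x) for analysis.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 kernel: int = 3, *, rng: np.random.Generator,
                 dtype=np.float32, post_activation: bool = True):
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        pad = kernel // 2
        self.conv1 = Conv2d(in_channels, out_channels, kernel, stride, pad,
                            rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(out_channels, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, kernel, 1, pad,
                            rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(out_channels, dtype=dtype)
        self.projection = stride != 1 or in_channels != out_channels
        if self.projection:
            self.proj_conv = Conv2d(in_channels, out_channels, 1, stride, 0,
                                    rng=rng, dtype=dtype)
            self.proj_bn = BatchNorm2d(out_channels, dtype=dtype)
        self.post_activation = post_activation
        self.relu_out = ReLU()
        self.stride = stride
        self.in_channels = in_channels
        self.out_channels = out_channels

    def branch_forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        return self.bn2.forward(h, train)

    def shortcut_forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not self.projection:
            return x
        return self.proj_bn.forward(self.proj_conv.forward(x, train), train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"residual unit expects {self.in_channels} input channels, "
                f"got shape {x.shape}")
        out = self.branch_forward(x, train) + self.shortcut_forward(x, train)
        if self.post_activation:
            out = self.relu_out.forward(out, train)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.post_activation:
            dy = self.relu_out.backward(dy)
        # branch path
        d = self.bn2.backward(dy)
        d = self.conv2.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        dx = self.conv1.backward(d)
        # shortcut path
        if self.projection:
            ds = self.proj_bn.backward(dy)
            dx = dx + self.proj_conv.backward(ds)
        else:
            dx = dx + dy
        return dx

    def zero_branch(self) -> None:
        """Zero the residual branch so the unit computes activation(shortcut(x))."""
        for mod in (self.conv1, self.conv2, self.bn1, self.bn2):
            for p in mod.parameters():
                p.data[...] = 0.0

    def parameters(self):
        params = (self.conv1.parameters() + self.bn1.parameters()
                  + self.conv2.parameters() + self.bn2.parameters())
        if self.projection:
            params += self.proj_conv.parameters() + self.proj_bn.parameters()
        return params

    def buffers(self):
        bufs = self.bn1.buffers() + self.bn2.buffers()
        if self.projection:
            bufs += self.proj_bn.buffers()
        return bufs
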