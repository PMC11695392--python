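"""Layers with explicit forward/backward passes.

Array layout is NCHW for spatial layers and (N, features) for dense layers.
Convolutions are evaluated as a sum of per-kernel-offset matrix products
(one ``tensordot`` per tap), which keeps both passes as large BLAS calls
without materialising an im2col buffer.
"""

from __future__ import annotations

import math

import numpy as np


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-learnable state (running statistics); same order across calls."""
        return []

    def set_buffers(self, values: list[np.ndarray]) -> None:
        own = self.buffers()
        for dst, src in zip(own, values):
            dst[...] = src


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
               dtype=np.float32) -> np.ndarray:
    limit = math.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv2d(Layer):
    """3x3 (or 1x1) convolution with 'same' zero padding, stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            he_uniform(rng, (out_channels, in_channels, kernel_size, kernel_size),
                       fan_in, dtype),
            "conv.weight",
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype), "conv.bias")
        self._x_pad: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        N, C, H, W = x.shape
        p = self.pad
        if p:
            x_pad = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=x.dtype)
            x_pad[:, :, p:-p, p:-p] = x
        else:
            x_pad = x
        self._x_pad = x_pad
        w = self.weight.value
        out = np.zeros((N, H, W, self.out_channels), dtype=x.dtype)
        for di in range(self.k):
            for dj in range(self.k):
                patch = x_pad[:, :, di:di + H, dj:dj + W]
                # (N,C,H,W) x (F,C) summed over C -> (N,H,W,F)
                out += np.tensordot(patch, w[:, :, di, dj], axes=([1], [1]))
        out += self.bias.value
        return np.ascontiguousarray(np.moveaxis(out, 3, 1))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_pad = self._x_pad
        N, F, H, W = grad.shape
        p = self.pad
        g = np.moveaxis(grad, 1, 3)  # (N,H,W,F)
        self.bias.grad += g.sum(axis=(0, 1, 2))
        w = self.weight.value
        dx_pad = np.zeros_like(x_pad)
        for di in range(self.k):
            for dj in range(self.k):
                patch = x_pad[:, :, di:di + H, dj:dj + W]
                # dW[f,c,di,dj] = sum_{n,h,w} g[n,h,w,f] * patch[n,c,h,w]
                self.weight.grad[:, :, di, dj] += np.tensordot(
                    g, patch, axes=([0, 1, 2], [0, 2, 3])
                )
                # dx_pad += g @ W  over F
                dx_pad[:, :, di:di + H, dj:dj + W] += np.moveaxis(
                    np.tensordot(g, w[:, :, di, dj], axes=([3], [0])), 3, 1
                )
        self._x_pad = None
        if p:
            return dx_pad[:, :, p:-p, p:-p]
        return dx_pad


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (axis 1).

    Works for both (N, C, H, W) and (N, C) inputs.  Training uses batch
    statistics and updates exponential running averages; evaluation uses the
    running statistics.
    """

    def __init__(self, num_features: int, momentum: float = 0.9,
                 eps: float = 1e-5, dtype=np.float32) -> None:
        self.gamma = Parameter(np.ones(num_features, dtype=dtype), "bn.gamma")
        self.beta = Parameter(np.zeros(num_features, dtype=dtype), "bn.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    @staticmethod
    def _expand(v: np.ndarray, ndim: int) -> np.ndarray:
        return v.reshape((1, -1) + (1,) * (ndim - 2))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - self._expand(mean, x.ndim)) * self._expand(inv_std, x.ndim)
        if training:
            self._cache = (x_hat, inv_std, axes)
        return self._expand(self.gamma.value, x.ndim) * x_hat + self._expand(
            self.beta.value, x.ndim
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_hat, inv_std, axes = self._cache
        self._cache = None
        m = np.prod([grad.shape[a] for a in axes])
        dgamma = (grad * x_hat).sum(axis=axes)
        dbeta = grad.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = grad * self._expand(self.gamma.value, grad.ndim)
        # standard batch-norm backward expressed in terms of x_hat
        dx = (
            g
            - self._expand(g.sum(axis=axes) / m, grad.ndim)
            - x_hat * self._expand((g * x_hat).sum(axis=axes) / m, grad.ndim)
        ) * self._expand(inv_std, grad.ndim)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask = self._mask
        self._mask = None
        return grad * mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        windows = x.reshape(N, C, H // 2, 2, W // 2, 2)
        windows = windows.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
        self._argmax = windows.argmax(axis=-1)
        self._in_shape = (N, C, H, W)
        return windows.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, W = self._in_shape
        out = np.zeros((N, C, H // 2, W // 2, 4), dtype=grad.dtype)
        np.put_along_axis(out, self._argmax[..., None], grad[..., None], axis=-1)
        self._argmax = None
        out = out.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(N, C, H, W)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        shape = self._shape
        self._shape = None
        return grad.reshape(shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        self.weight = Parameter(
            he_uniform(rng, (in_features, out_features), in_features, dtype),
            "dense.weight",
        )
        self.bias = Parameter(np.zeros(out_features, dtype=dtype), "dense.bias")

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        self.weight.grad += x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        mask = self._mask
        self._mask = None
        return grad * mask


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def buffers(self) -> list[np.ndarray]:
        return [b for layer in self.layers for b in layer.buffers()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Residual(Layer):
    """Two-branch residual composition: output = main(x) + skip(x)."""

    def __init__(self, main: Layer, skip: Layer) -> None:
        self.main = main
        self.skip = skip

    def parameters(self) -> list[Parameter]:
        return self.main.parameters() + self.skip.parameters()

    def buffers(self) -> list[np.ndarray]:
        return self.main.buffers() + self.skip.buffers()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.main.forward(x, training) + self.skip.forward(x, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.main.backward(grad) + self.skip.backward(grad)
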