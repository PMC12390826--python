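"""A compact numpy CNN engine: layers with explicit forward/backward passes.

Every layer is a :class:`Module` holding named :class:`Param` objects.
``forward`` caches whatever the matching ``backward`` needs; ``backward``
receives the gradient w.r.t. the layer output, accumulates parameter
gradients in ``Param.grad`` and returns the gradient w.r.t. the input.
Convolution is evaluated as an im2col matrix product, which keeps the hot
loop inside BLAS.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .functional import conv_output_size


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class; submodules and params are discovered from attributes."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Param]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if prefix else name
            if isinstance(value, Param):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def parameters(self) -> Iterator[Param]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        """Non-trainable state (batch-norm running statistics)."""
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if prefix else name
            if isinstance(value, Module):
                yield from value.named_buffers(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(prefix=f"{full}.{i}.")
        for name in getattr(self, "_buffer_names", ()):
            full = f"{prefix}{name}" if prefix else name
            yield full, getattr(self, name)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({name: buf for name, buf in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name: name for name, _ in self.named_buffers()}
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for parameter {key!r}")
                params[key].data[...] = value
            elif key in buffers:
                self._assign_buffer(key, value)
            # unknown keys (e.g. attention weights loaded into a plain
            # backbone) are ignored so backbone weights transfer cleanly

    def _assign_buffer(self, dotted: str, value: np.ndarray) -> None:
        obj: Module = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        getattr(obj, parts[-1])[...] = value


def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, dtype=np.float32) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv2d(Module):
    """2D convolution with stride, zero padding and dilation (no groups)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = False, *, rng: np.random.Generator,
                 dtype=np.float32):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        fan_in = in_channels * kernel * kernel
        self.weight = Param(kaiming_normal(
            rng, (out_channels, in_channels, kernel, kernel), fan_in, dtype))
        self.bias = Param(np.zeros(out_channels, dtype=dtype)) if bias else None
        self._cache = None

    def _im2col(self, xp: np.ndarray, h_out: int, w_out: int) -> np.ndarray:
        b = xp.shape[0]
        k, s, d = self.kernel, self.stride, self.dilation
        cols = np.empty(
            (b, self.in_channels, k, k, h_out, w_out), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[
                    :, :,
                    i * d: i * d + (h_out - 1) * s + 1: s,
                    j * d: j * d + (w_out - 1) * s + 1: s,
                ]
        return cols

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {c}")
        k = self.kernel
        eff = self.dilation * (k - 1) + 1
        if h + 2 * self.padding < eff:
            raise ValueError(
                f"input height {h} smaller than effective kernel {eff}")
        if w + 2 * self.padding < eff:
            raise ValueError(
                f"input width {w} smaller than effective kernel {eff}")
        h_out = conv_output_size(h, k, self.stride, self.padding, self.dilation)
        w_out = conv_output_size(w, k, self.stride, self.padding, self.dilation)
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = self._im2col(xp, h_out, w_out)
        mat = cols.reshape(b, self.in_channels * k * k, h_out * w_out)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        y = np.matmul(wmat[None], mat)
        y = y.reshape(b, self.out_channels, h_out, w_out)
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        self._cache = (mat, x.shape, h_out, w_out)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mat, x_shape, h_out, w_out = self._cache
        b, c, h, w = x_shape
        k, s, d, p = self.kernel, self.stride, self.dilation, self.padding
        gmat = grad.reshape(b, self.out_channels, h_out * w_out)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        self.weight.grad += np.einsum(
            "bop,bfp->of", gmat, mat, optimize=True).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        dcols = np.einsum("of,bop->bfp", wmat, gmat, optimize=True)
        dcols = dcols.reshape(b, c, k, k, h_out, w_out)
        gxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                gxp[:, :,
                    i * d: i * d + (h_out - 1) * s + 1: s,
                    j * d: j * d + (w_out - 1) * s + 1: s] += dcols[:, :, i, j]
        return gxp[:, :, p: p + h, p: p + w] if p else gxp


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, training, x.shape)
        return self.gamma.data[None, :, None, None] * xhat \
            + self.beta.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, training, x_shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        if not training:
            return g * inv_std[None, :, None, None]
        b, _, h, w = x_shape
        n = b * h * w
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std[None, :, None, None] / n) * (
            n * g - sum_g - xhat * sum_gx)


class ReLU(Module):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        h_out = conv_output_size(h, k, s, p)
        w_out = conv_output_size(w, k, s, p)
        xp = np.full((b, c, h + 2 * p, w + 2 * p), -np.inf, dtype=x.dtype)
        xp[:, :, p: p + h, p: p + w] = x
        stack = np.empty((k * k, b, c, h_out, w_out), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                stack[i * k + j] = xp[:, :,
                                      i: i + (h_out - 1) * s + 1: s,
                                      j: j + (w_out - 1) * s + 1: s]
        arg = stack.argmax(axis=0)
        out = np.take_along_axis(stack, arg[None], axis=0)[0]
        self._cache = (arg, x.shape, h_out, w_out)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        arg, x_shape, h_out, w_out = self._cache
        b, c, h, w = x_shape
        k, s, p = self.kernel, self.stride, self.padding
        gxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                mask = arg == i * k + j
                view = gxp[:, :,
                           i: i + (h_out - 1) * s + 1: s,
                           j: j + (w_out - 1) * s + 1: s]
                view += np.where(mask, grad, 0.0)
        return gxp[:, :, p: p + h, p: p + w] if p else gxp


class GlobalAvgPool(Module):
    """Average pooling over all spatial positions, keeping (B, C)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.broadcast_to(
            grad[:, :, None, None] / (h * w), self._shape).copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator, dtype=np.float32):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Param(kaiming_normal(
            rng, (out_features, in_features), in_features, dtype))
        self.bias = Param(np.zeros(out_features, dtype=dtype))
        self._x = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.layers = list(modules)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
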