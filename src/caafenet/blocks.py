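"""Building blocks of the channel-attention-augmented residual classifier.

The CAAFE block decomposes a feature map into three parallel serial-dilated
convolution branches (dilation schedules (1,1), (1,2,3) and (1,3,5)), each
fused back to the input width by a 1x1 convolution with batch normalisation,
and adds a channel-attention path; the four outputs are summed elementwise,
so the block preserves its input shape exactly.  The stem (CBRM) and the
residual unit follow a modified ResNet18: the residual unit applies ReLU
*before* the additive skip by default, with a ``canonical`` flag restoring
the usual post-addition placement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn.functional import log_softmax, sigmoid
from .nn.layers import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    Param,
    ReLU,
)


class ConfigurationError(ValueError):
    """Raised when a block is assembled with incompatible settings."""


@dataclass
class CAMConfig:
    """Channel-attention settings: bottleneck width = max(1, C // reduction)."""
    channels: int
    reduction_ratio: int = 16


@dataclass
class CAAFEBlockSpec:
    """Shape contract of one CAAFE block at width ``channels``."""
    channels: int
    branch1_dilations: tuple[int, ...] = (1, 1)
    branch2_dilations: tuple[int, ...] = (1, 2, 3)
    branch3_dilations: tuple[int, ...] = (1, 3, 5)
    inter_conv_activation: bool = True
    branch1_include_input: bool = False
    cam: CAMConfig | None = None

    def __post_init__(self):
        if self.cam is None:
            self.cam = CAMConfig(channels=self.channels)


class CBRM(Module):
    """Stem: Conv -> BatchNorm -> ReLU -> MaxPool.

    ``variant="standard"`` uses the ResNet18 geometry (7x7, stride 2,
    padding 3; 3x3 max-pool, stride 2, padding 1), so a 256x256 input maps
    to 64x64.  ``variant="literal"`` uses a 7x7 convolution with stride 1
    and no padding.
    """

    def __init__(self, in_channels: int = 1, out_channels: int = 64,
                 variant: str = "standard", *, rng: np.random.Generator):
        if variant not in ("standard", "literal"):
            raise ConfigurationError(
                f"unknown stem variant {variant!r}; choose standard|literal")
        stride, padding = (2, 3) if variant == "standard" else (1, 0)
        self.variant = variant
        self.conv = Conv2d(in_channels, out_channels, 7, stride=stride,
                           padding=padding, rng=rng)
        self.bn = BatchNorm2d(out_channels)
        self.relu = ReLU()
        self.pool = MaxPool2d(3, stride=2, padding=1)

    def forward(self, x, training=False):
        h = self.conv.forward(x, training)
        h = self.bn.forward(h, training)
        h = self.relu.forward(h, training)
        return self.pool.forward(h, training)

    def backward(self, grad):
        grad = self.pool.backward(grad)
        grad = self.relu.backward(grad)
        grad = self.bn.backward(grad)
        return self.conv.backward(grad)


class ResidualUnit(Module):
    """Two 3x3 conv->BN->ReLU layers plus an identity (or projection) skip.

    With ``preadd_relu=True`` the second ReLU is applied before the addition
    (y = (ReLU(BN(Conv(.))))^2 + x); with ``False`` the canonical ResNet
    ordering is used (addition first, then ReLU).  Stage entry units use
    stride 2 and a 1x1 projection shortcut.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 preadd_relu: bool = True, projection: bool | None = None,
                 *, rng: np.random.Generator):
        needs_projection = (in_channels != out_channels) or stride != 1
        if projection is None:
            projection = needs_projection
        if needs_projection and not projection:
            raise ConfigurationError(
                f"residual unit {in_channels}->{out_channels} (stride "
                f"{stride}) requires a projection shortcut")
        self.preadd_relu = preadd_relu
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride=stride,
                            padding=1, rng=rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, 3, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(out_channels)
        self.relu2 = ReLU()
        if projection:
            self.proj_conv = Conv2d(in_channels, out_channels, 1,
                                    stride=stride, rng=rng)
            self.proj_bn = BatchNorm2d(out_channels)
        else:
            self.proj_conv = None
            self.proj_bn = None

    def forward(self, x, training=False):
        h = self.relu1.forward(self.bn1.forward(
            self.conv1.forward(x, training), training), training)
        h = self.bn2.forward(self.conv2.forward(h, training), training)
        if self.proj_conv is not None:
            shortcut = self.proj_bn.forward(
                self.proj_conv.forward(x, training), training)
        else:
            shortcut = x
        if self.preadd_relu:
            return self.relu2.forward(h, training) + shortcut
        return self.relu2.forward(h + shortcut, training)

    def backward(self, grad):
        if self.preadd_relu:
            g_main = self.relu2.backward(grad)
            g_short = grad
        else:
            g = self.relu2.backward(grad)
            g_main, g_short = g, g
        g_main = self.conv2.backward(self.bn2.backward(g_main))
        g_main = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(g_main)))
        if self.proj_conv is not None:
            g_short = self.proj_conv.backward(self.proj_bn.backward(g_short))
        return g_main + g_short


class _SharedBottleneck:
    """Two-layer perceptron shared between pooled channel descriptors."""

    def __init__(self, channels: int, hidden: int, rng, dtype=np.float32):
        std1 = np.sqrt(2.0 / channels)
        std2 = np.sqrt(2.0 / hidden)
        self.w1 = Param(rng.normal(0, std1, (hidden, channels)).astype(dtype))
        self.b1 = Param(np.zeros(hidden, dtype=dtype))
        self.w2 = Param(rng.normal(0, std2, (channels, hidden)).astype(dtype))
        self.b2 = Param(np.zeros(channels, dtype=dtype))

    def forward(self, d):
        a = d @ self.w1.data.T + self.b1.data
        h = np.maximum(a, 0.0)
        o = h @ self.w2.data.T + self.b2.data
        return o, (d, a, h)

    def backward(self, do, cache):
        d, a, h = cache
        self.w2.grad += do.T @ h
        self.b2.grad += do.sum(axis=0)
        dh = do @ self.w2.data
        da = np.where(a > 0, dh, 0.0)
        self.w1.grad += da.T @ d
        self.b1.grad += da.sum(axis=0)
        return da @ self.w1.data


class ChannelAttention(Module):
    """Channel attention: sigmoid(MLP(avgpool) + MLP(maxpool)) channel gates.

    The gate is strictly inside (0, 1); a zeroed bottleneck yields exactly
    0.5 per channel.  The two pooled descriptors share one bottleneck.
    """

    def __init__(self, cfg: CAMConfig, *, rng: np.random.Generator):
        c, r = cfg.channels, cfg.reduction_ratio
        if r > c:
            warnings.warn(
                f"reduction ratio {r} exceeds channel count {c}; "
                "bottleneck width clamped to 1", RuntimeWarning, stacklevel=2)
        self.cfg = cfg
        self.hidden = max(1, c // r)
        self.mlp = _SharedBottleneck(c, self.hidden, rng)
        self._cache = None

    def named_parameters(self, prefix: str = ""):
        for name in ("w1", "b1", "w2", "b2"):
            yield f"{prefix}mlp.{name}", getattr(self.mlp, name)

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Per-channel gate values in (0,1) for a feature map, shape (B,C)."""
        avg = x.mean(axis=(2, 3))
        mx = x.reshape(*x.shape[:2], -1).max(axis=-1)
        o_avg, _ = self.mlp.forward(avg)
        o_max, _ = self.mlp.forward(mx)
        return sigmoid(o_avg + o_max)

    def forward(self, x, training=False):
        b, c, h, w = x.shape
        if c != self.cfg.channels:
            raise ConfigurationError(
                f"channel attention built for {self.cfg.channels} channels, "
                f"got {c}")
        avg = x.mean(axis=(2, 3))
        flat = x.reshape(b, c, h * w)
        idx = flat.argmax(axis=-1)
        mx = np.take_along_axis(flat, idx[:, :, None], axis=-1)[:, :, 0]
        o_avg, cache_avg = self.mlp.forward(avg)
        o_max, cache_max = self.mlp.forward(mx)
        gate = sigmoid(o_avg + o_max)
        self._cache = (x, gate, idx, cache_avg, cache_max)
        return x * gate[:, :, None, None]

    def backward(self, grad):
        x, gate, idx, cache_avg, cache_max = self._cache
        b, c, h, w = x.shape
        dx = grad * gate[:, :, None, None]
        dgate = (grad * x).sum(axis=(2, 3))
        dlogit = dgate * gate * (1.0 - gate)
        d_avg = self.mlp.backward(dlogit, cache_avg)
        d_max = self.mlp.backward(dlogit, cache_max)
        dx += d_avg[:, :, None, None] / (h * w)
        dxf = dx.reshape(b, c, h * w)
        np.put_along_axis(
            dxf, idx[:, :, None],
            np.take_along_axis(dxf, idx[:, :, None], -1) + d_max[:, :, None],
            -1)
        return dxf.reshape(b, c, h, w)


class CAAFEBranch(Module):
    """One serial-dilated branch: 3x3 convs (padding = dilation), channel
    concatenation of the intermediate outputs, 1x1 fuse and batch norm."""

    def __init__(self, channels: int, dilations: tuple[int, ...],
                 activation: bool = True, include_input: bool = False,
                 *, rng: np.random.Generator):
        self.channels = channels
        self.dilations = tuple(dilations)
        self.activation = activation
        self.include_input = include_input
        self.convs = [
            Conv2d(channels, channels, 3, padding=d, dilation=d, rng=rng)
            for d in self.dilations
        ]
        self.relus = [ReLU() for _ in self.dilations]
        arity = len(self.dilations) + (1 if include_input else 0)
        self.fuse = Conv2d(arity * channels, channels, 1, rng=rng)
        self.bn = BatchNorm2d(channels)

    def serial_outputs(self, x, training=False):
        outs = []
        h = x
        for conv, relu in zip(self.convs, self.relus):
            h = conv.forward(h, training)
            if self.activation:
                h = relu.forward(h, training)
            outs.append(h)
        return outs

    def forward(self, x, training=False):
        outs = self.serial_outputs(x, training)
        parts = ([x] + outs) if self.include_input else outs
        cat = np.concatenate(parts, axis=1)
        return self.bn.forward(self.fuse.forward(cat, training), training)

    def backward(self, grad):
        c = self.channels
        dcat = self.fuse.backward(self.bn.backward(grad))
        chunks = [dcat[:, i * c:(i + 1) * c] for i in range(dcat.shape[1] // c)]
        dx_direct = chunks.pop(0) if self.include_input else 0.0
        g = chunks[-1]
        for k in range(len(self.convs) - 1, -1, -1):
            if self.activation:
                g = self.relus[k].backward(g)
            g = self.convs[k].backward(g)
            if k > 0:
                g = g + chunks[k - 1]
        return g + dx_direct


class CAAFEBlock(Module):
    """Sum of the three dilated branches and the channel-attention path."""

    def __init__(self, spec: CAAFEBlockSpec, *, rng: np.random.Generator):
        self.spec = spec
        act = spec.inter_conv_activation
        self.branch1 = CAAFEBranch(spec.channels, spec.branch1_dilations,
                                   activation=act,
                                   include_input=spec.branch1_include_input,
                                   rng=rng)
        self.branch2 = CAAFEBranch(spec.channels, spec.branch2_dilations,
                                   activation=act, rng=rng)
        self.branch3 = CAAFEBranch(spec.channels, spec.branch3_dilations,
                                   activation=act, rng=rng)
        self.cam = ChannelAttention(spec.cam, rng=rng)

    def forward(self, x, training=False):
        f1 = self.branch1.forward(x, training)
        f2 = self.branch2.forward(x, training)
        f3 = self.branch3.forward(x, training)
        f4 = self.cam.forward(x, training)
        for name, f in (("branch1", f1), ("branch2", f2),
                        ("branch3", f3), ("cam", f4)):
            assert f.shape == x.shape, \
                f"{name} changed the feature-map shape: {f.shape} != {x.shape}"
        return f1 + f2 + f3 + f4

    def backward(self, grad):
        return (self.branch1.backward(grad) + self.branch2.backward(grad)
                + self.branch3.backward(grad) + self.cam.backward(grad))


class SEBlock(Module):
    """Squeeze-and-excitation: sigmoid(MLP(avgpool)) channel gates."""

    def __init__(self, channels: int, reduction_ratio: int = 16,
                 *, rng: np.random.Generator):
        self.channels = channels
        hidden = max(1, channels // reduction_ratio)
        self.mlp = _SharedBottleneck(channels, hidden, rng)
        self._cache = None

    def named_parameters(self, prefix: str = ""):
        for name in ("w1", "b1", "w2", "b2"):
            yield f"{prefix}mlp.{name}", getattr(self.mlp, name)

    def forward(self, x, training=False):
        avg = x.mean(axis=(2, 3))
        o, cache = self.mlp.forward(avg)
        gate = sigmoid(o)
        self._cache = (x, gate, cache)
        return x * gate[:, :, None, None]

    def backward(self, grad):
        x, gate, cache = self._cache
        h, w = x.shape[2:]
        dx = grad * gate[:, :, None, None]
        dgate = (grad * x).sum(axis=(2, 3))
        dlogit = dgate * gate * (1.0 - gate)
        d_avg = self.mlp.backward(dlogit, cache)
        return dx + d_avg[:, :, None, None] / (h * w)


class CBAMBlock(Module):
    """Channel attention followed by a 7x7 spatial-attention gate."""

    def __init__(self, channels: int, reduction_ratio: int = 16,
                 *, rng: np.random.Generator):
        self.channel = ChannelAttention(
            CAMConfig(channels, reduction_ratio), rng=rng)
        self.spatial_conv = Conv2d(2, 1, 7, padding=3, rng=rng)
        self._cache = None

    def forward(self, x, training=False):
        h = self.channel.forward(x, training)
        avg_c = h.mean(axis=1, keepdims=True)
        idx = h.argmax(axis=1)
        max_c = np.take_along_axis(h, idx[:, None], axis=1)
        desc = np.concatenate([avg_c, max_c], axis=1)
        logit = self.spatial_conv.forward(desc, training)
        gate = sigmoid(logit)
        self._cache = (h, gate, idx)
        return h * gate

    def backward(self, grad):
        h, gate, idx = self._cache
        c = h.shape[1]
        dh = grad * gate
        dgate = (grad * h).sum(axis=1, keepdims=True)
        dlogit = dgate * gate * (1.0 - gate)
        ddesc = self.spatial_conv.backward(dlogit)
        dh += ddesc[:, :1] / c
        np.put_along_axis(
            dh, idx[:, None],
            np.take_along_axis(dh, idx[:, None], axis=1) + ddesc[:, 1:2],
            axis=1)
        return self.channel.backward(dh)


class ClassifierHead(Module):
    """Global average pooling, affine map to class logits, LogSoftmax."""

    def __init__(self, in_channels: int, n_classes: int = 2,
                 *, rng: np.random.Generator):
        self.pool = GlobalAvgPool()
        self.fc = Linear(in_channels, n_classes, rng=rng)
        self._softmax = None

    def forward(self, z, training=False):
        logits = self.fc.forward(self.pool.forward(z, training), training)
        logp = log_softmax(logits, axis=1)
        self._softmax = np.exp(logp)
        return logp

    def backward(self, grad):
        dlogits = grad - self._softmax * grad.sum(axis=1, keepdims=True)
        return self.pool.backward(self.fc.backward(dlogits))
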