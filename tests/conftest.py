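"""Shared fixtures and independent oracles.

The convolution oracle here is a deliberately naive nested-loop
implementation, kept separate from the package's im2col path so the two
can be compared on small inputs.
"""

from __future__ import annotations

import numpy as np
import pytest


def naive_conv2d(x, w, stride=1, padding=0, dilation=1):
    """Direct nested-loop 2D convolution (cross-correlation)."""
    b_n, c_in, h, w_in = x.shape
    c_out, _, k, _ = w.shape
    p, s, d = padding, stride, dilation
    xp = np.zeros((b_n, c_in, h + 2 * p, w_in + 2 * p), dtype=np.float64)
    xp[:, :, p:p + h, p:p + w_in] = x
    h_out = (h + 2 * p - d * (k - 1) - 1) // s + 1
    w_out = (w_in + 2 * p - d * (k - 1) - 1) // s + 1
    out = np.zeros((b_n, c_out, h_out, w_out))
    for b in range(b_n):
        for o in range(c_out):
            for i in range(h_out):
                for j in range(w_out):
                    acc = 0.0
                    for c in range(c_in):
                        for u in range(k):
                            for v in range(k):
                                acc += (xp[b, c, i * s + u * d, j * s + v * d]
                                        * w[o, c, u, v])
                    out[b, o, i, j] = acc
    return out


def naive_bn_eval(x, gamma, beta, running_mean, running_var, eps=1e-5):
    inv = 1.0 / np.sqrt(running_var + eps)
    return (x - running_mean[None, :, None, None]) \
        * inv[None, :, None, None] * gamma[None, :, None, None] \
        + beta[None, :, None, None]


def oracle_branch(x, branch):
    """Straight-line re-evaluation of one dilated branch from its weights."""
    outs, h = [], x
    for conv, d in zip(branch.convs, branch.dilations):
        h = naive_conv2d(h, conv.weight.data.astype(np.float64),
                         padding=d, dilation=d)
        if branch.activation:
            h = np.maximum(h, 0.0)
        outs.append(h)
    parts = ([x] + outs) if branch.include_input else outs
    cat = np.concatenate(parts, axis=1)
    fused = naive_conv2d(cat, branch.fuse.weight.data.astype(np.float64))
    bn = branch.bn
    return naive_bn_eval(fused, bn.gamma.data.astype(np.float64),
                         bn.beta.data.astype(np.float64),
                         bn.running_mean.astype(np.float64),
                         bn.running_var.astype(np.float64), bn.eps)


def oracle_cam(x, cam):
    """Closed-form channel attention from the module's raw weights."""
    mlp = cam.mlp
    avg = x.mean(axis=(2, 3))
    mx = x.reshape(*x.shape[:2], -1).max(axis=-1)

    def bottleneck(d):
        hdn = np.maximum(d @ mlp.w1.data.T.astype(np.float64)
                         + mlp.b1.data.astype(np.float64), 0.0)
        return hdn @ mlp.w2.data.T.astype(np.float64) \
            + mlp.b2.data.astype(np.float64)

    logit = bottleneck(avg) + bottleneck(mx)
    gate = 1.0 / (1.0 + np.exp(-logit))
    return x * gate[:, :, None, None]


def oracle_caafe(x, block):
    """Straight-line re-evaluation of the whole CAAFE block."""
    return (oracle_branch(x, block.branch1) + oracle_branch(x, block.branch2)
            + oracle_branch(x, block.branch3) + oracle_cam(x, block.cam))


def to_float64(module):
    """Cast a module's parameters and buffers to float64 for grad checks."""
    for _, p in module.named_parameters():
        p.data = p.data.astype(np.float64)
        p.grad = np.zeros_like(p.data)
    for name, _ in module.named_buffers():
        obj, parts = module, name.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        setattr(obj, parts[-1],
                getattr(obj, parts[-1]).astype(np.float64))
    return module


def numeric_input_gradient(module, x, grad_out, eps=1e-6, training=False):
    """Central finite-difference gradient of sum(out * grad_out) w.r.t. x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        fp = float((module.forward(xp, training=training) * grad_out).sum())
        fm = float((module.forward(xm, training=training) * grad_out).sum())
        g[idx] = (fp - fm) / (2 * eps)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
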