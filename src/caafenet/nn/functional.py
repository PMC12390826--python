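"""Stateless numeric primitives shared by the layer classes."""

from __future__ import annotations

import numpy as np


def log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable log-softmax: ``x_i - log(sum_j exp(x_j))``.

    The maximum is subtracted before exponentiation so that large logits
    (e.g. 1000) do not overflow; the result is invariant under adding a
    constant to every entry.
    """
    x = np.asarray(x)
    if x.size == 0 or x.shape[axis] == 0:
        raise ValueError("log_softmax of an empty vector is undefined")
    m = np.max(x, axis=axis, keepdims=True)
    shifted = x - m
    lse = np.log(np.sum(np.exp(shifted), axis=axis, keepdims=True))
    return shifted - lse


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Logistic squashing, computed branch-wise to avoid overflow."""
    out = np.empty_like(x, dtype=np.result_type(x, np.float32))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def conv_output_size(size: int, kernel: int, stride: int, padding: int,
                     dilation: int = 1) -> int:
    """Spatial output extent of a convolution/pooling window."""
    eff = dilation * (kernel - 1) + 1
    out = (size + 2 * padding - eff) // stride + 1
    if out < 1:
        raise ValueError(
            f"window (kernel={kernel}, dilation={dilation}) does not fit "
            f"into spatial extent {size} with padding {padding}"
        )
    return out
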