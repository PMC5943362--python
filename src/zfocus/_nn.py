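"""Minimal NumPy layers for the autofocus CNN.

Convolutions are stride-1 with "same" zero padding and are evaluated as
im2col + BLAS matmul in float32; backward passes reuse the cached column
matrices (dW) and express the input gradient of a stride-1 convolution as a
convolution with the spatially flipped, channel-transposed kernel.  Max
pooling uses non-overlapping windows with floor semantics (trailing rows and
columns that do not fill a window are dropped).  Layout is channels-last:
``(batch, height, width, channels)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "same_pad",
    "conv2d_forward",
    "conv2d_backward",
    "maxpool_forward",
    "maxpool_backward",
    "relu",
    "log_softmax",
    "softmax",
    "cross_entropy_from_log_probs",
    "AdamState",
]


def same_pad(kernel: int) -> tuple[int, int]:
    """Asymmetric 'same' padding for stride 1: total pad = kernel − 1."""
    total = kernel - 1
    return total // 2, total - total // 2


def _im2col(x: np.ndarray, kernel: int, pad: tuple[int, int]) -> np.ndarray:
    """(B,H,W,C) → column matrix (B*H*W, kernel*kernel*C), stride 1."""
    xp = np.pad(x, ((0, 0), pad, pad, (0, 0)))
    # windows: (B, H, W, C, k, k) → reorder to (.., k, k, C) to match kernels
    win = sliding_window_view(xp, (kernel, kernel), axis=(1, 2))
    b, h, w = win.shape[:3]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(b * h * w, -1)
    return np.ascontiguousarray(cols, dtype=np.float32)


def conv2d_forward(x: np.ndarray, weights: np.ndarray, bias: np.ndarray):
    """Stride-1 same-padded convolution.

    ``weights`` has shape (k, k, c_in, c_out).  Returns (output, cols) where
    cols is the im2col matrix cached for the backward pass.
    """
    k, _, c_in, c_out = weights.shape
    cols = _im2col(x, k, same_pad(k))
    out = cols @ weights.reshape(-1, c_out) + bias
    b, h, w = x.shape[0], x.shape[1], x.shape[2]
    return out.reshape(b, h, w, c_out), cols


def conv2d_backward(
    d_out: np.ndarray,
    cols: np.ndarray,
    weights: np.ndarray,
    need_dx: bool = True,
):
    """Gradients of a stride-1 same-padded convolution.

    Returns (d_weights, d_bias, d_x); d_x is None when ``need_dx`` is False
    (the first layer never needs it).
    """
    k, _, c_in, c_out = weights.shape
    dy = d_out.reshape(-1, c_out)
    d_w = (cols.T @ dy).reshape(weights.shape)
    d_b = dy.sum(axis=0)
    d_x = None
    if need_dx:
        # input gradient = conv of d_out with the flipped kernel, channels swapped
        w_rot = weights[::-1, ::-1].transpose(0, 1, 3, 2)  # (k, k, c_out, c_in)
        pl, pr = same_pad(k)
        cols_back = _im2col(d_out, k, (k - 1 - pl, k - 1 - pr))
        b, h, w = d_out.shape[:3]
        d_x = (cols_back @ w_rot.reshape(-1, c_in)).reshape(b, h, w, c_in)
    return d_w, d_b, d_x


def maxpool_forward(x: np.ndarray, size: int):
    """Non-overlapping max pooling, stride = size, floor on the remainder.

    Returns (output, argmax) with argmax cached for the backward pass.
    """
    b, h, w, c = x.shape
    h2, w2 = h // size, w // size
    if h2 < 1 or w2 < 1:
        raise ValueError(f"feature map {h}x{w} smaller than pool size {size}")
    t = x[:, : h2 * size, : w2 * size, :]
    t = t.reshape(b, h2, size, w2, size, c).transpose(0, 1, 3, 2, 4, 5)
    flat = np.ascontiguousarray(t).reshape(b, h2, w2, size * size, c)
    idx = flat.argmax(axis=3)
    out = np.take_along_axis(flat, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, idx


def maxpool_backward(d_out: np.ndarray, idx: np.ndarray, x_shape, size: int):
    b, h, w, c = x_shape
    h2, w2 = h // size, w // size
    flat = np.zeros((b, h2, w2, size * size, c), dtype=d_out.dtype)
    np.put_along_axis(flat, idx[:, :, :, None, :], d_out[:, :, :, None, :], axis=3)
    t = flat.reshape(b, h2, w2, size, size, c).transpose(0, 1, 3, 2, 4, 5)
    d_x = np.zeros(x_shape, dtype=d_out.dtype)
    d_x[:, : h2 * size, : w2 * size, :] = t.reshape(b, h2 * size, w2 * size, c)
    return d_x


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def log_softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable log-softmax along the last axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(logits))


def cross_entropy_from_log_probs(log_p: np.ndarray, labels: np.ndarray) -> float:
    return float(-log_p[np.arange(len(labels)), labels].mean())


class AdamState:
    """Adam optimizer state over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float, beta1: float, beta2: float,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def update(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            params[k] -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
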