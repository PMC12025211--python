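"""Minimal NumPy layer primitives with hand-written backprop.

Everything operates on (N, C, H, W) float64 tensors. Convolutions are
3x3, stride 1, zero-padded "same"; the forward pass uses a zero-copy
sliding-window view contracted with einsum, and the input gradient is the
full correlation with the 180-degree-rotated kernels, so no scatter-add
(col2im) is ever needed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_EINSUM_KW = dict(optimize=True)


def he_init(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def conv3x3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3) view
    return np.einsum("nchwij,ocij->nohw", win, W, **_EINSUM_KW) + b[:, None, None]


def conv3x3_backward(x: np.ndarray, W: np.ndarray, dy: np.ndarray) -> tuple:
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))
    dW = np.einsum("nohw,nchwij->ocij", dy, win, **_EINSUM_KW)
    db = dy.sum(axis=(0, 2, 3))
    dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dwin = sliding_window_view(dyp, (3, 3), axis=(2, 3))
    Wf = W[:, :, ::-1, ::-1]
    dx = np.einsum("nohwij,ocij->nchw", dwin, Wf, **_EINSUM_KW)
    return dx, dW, db


def conv1x1_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    # W: (Cout, Cin)
    return np.einsum("nchw,oc->nohw", x, W, **_EINSUM_KW) + b[:, None, None]


def conv1x1_backward(x: np.ndarray, W: np.ndarray, dy: np.ndarray) -> tuple:
    dW = np.einsum("nohw,nchw->oc", dy, x, **_EINSUM_KW)
    db = dy.sum(axis=(0, 2, 3))
    dx = np.einsum("nohw,oc->nchw", dy, W, **_EINSUM_KW)
    return dx, dW, db


def relu_forward(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(y: np.ndarray, dy: np.ndarray) -> np.ndarray:
    return dy * (y > 0)


def maxpool2_forward(x: np.ndarray) -> tuple:
    n, c, h, w = x.shape
    r = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = r.max(axis=(3, 5))
    return out, r


def maxpool2_backward(r: np.ndarray, out: np.ndarray, dy: np.ndarray) -> np.ndarray:
    # gradient split equally among tied maxima (deterministic)
    mask = r == out[:, :, :, None, :, None]
    counts = mask.sum(axis=(3, 5))
    dr = mask * (dy / counts)[:, :, :, None, :, None]
    n, c, h2, _, w2, _ = r.shape
    return dr.reshape(n, c, h2 * 2, w2 * 2)


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_softmax_ce(logits: np.ndarray, labels: np.ndarray,
                        class_weights: np.ndarray) -> tuple:
    """Weighted cross-entropy over rows of (M, K) logits.

    Returns (loss, dlogits) with loss = mean_i -w_{y_i} log p_{i,y_i} and
    dlogits_i = w_{y_i} (p_i - onehot_i) / M.
    """
    p = softmax(logits)
    m = len(labels)
    w = class_weights[labels]
    p_true = np.clip(p[np.arange(m), labels], 1e-12, None)
    loss = float(np.mean(-w * np.log(p_true)))
    dlogits = p.copy()
    dlogits[np.arange(m), labels] -= 1.0
    dlogits *= (w / m)[:, None]
    return loss, dlogits
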