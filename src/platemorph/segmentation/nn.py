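"""Minimal NumPy convolutional encoder-decoder with explicit backprop.

Implements exactly what the desk-scale segmenter needs: 3x3/1x1 "same"
convolutions, ReLU, 2x2 max pooling, nearest-neighbour upsampling, skip
concatenation, and a sigmoid + binary-cross-entropy head, trained with
Adam.  All state lives in plain ``dict[str, ndarray]`` parameter maps so
models serialize to ``.npz`` without any framework dependency.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

Params = dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# primitive layers


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padding cross-correlation. x: (N,C,H,W); w: (F,C,k,k)."""
    k = w.shape[2]
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))
    y = np.einsum("nchwij,fcij->nfhw", win, w, optimize=True)
    return y + b[None, :, None, None]


def conv2d_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) for :func:`conv2d`."""
    k = w.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    dw = np.einsum("nchwij,nfhw->fcij", win, dy, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p))) if p else dy
    win_dy = sliding_window_view(dyp, (k, k), axis=(2, 3))
    w_flip = w[:, :, ::-1, ::-1]
    dx = np.einsum("nfhwij,fcij->nchw", win_dy, w_flip, optimize=True)
    return dx, dw, db


def maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pooling; returns pooled output and the argmax mask."""
    n, c, h, w = x.shape
    r = x.reshape(n, c, h // 2, 2, w // 2, 2)
    y = r.max(axis=(3, 5))
    mask = r == y[:, :, :, None, :, None]
    # break ties so each window routes gradient to exactly one element
    flat = mask.reshape(n, c, h // 2, w // 2, 4)
    first = np.argmax(flat, axis=-1)
    mask = np.eye(4, dtype=bool)[first].reshape(n, c, h // 2, w // 2, 2, 2)
    mask = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
    return y, mask


def maxpool2_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n, c, h2, w2 = dy.shape
    up = dy[:, :, :, None, :, None]
    up = np.broadcast_to(up, (n, c, h2, 2, w2, 2)).reshape(n, c, 2 * h2, 2 * w2)
    return up * mask


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dlogits)."""
    p = sigmoid(logits)
    eps = 1e-12
    loss = -np.mean(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps))
    dlogits = (p - targets) / logits.size
    return float(loss), dlogits


# ---------------------------------------------------------------------------
# encoder-decoder network


def _filters(base: int, depth: int) -> list[int]:
    return [base * 2**i for i in range(depth)]


def init_params(depth: int, base_filters: int, rng: np.random.Generator,
                in_channels: int = 1) -> Params:
    """He-initialized parameters for the contracting/expanding net."""
    params: Params = {}

    def he(fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    filts = _filters(base_filters, depth)
    c = in_channels
    for i, f in enumerate(filts):
        params[f"enc{i}_w1"] = he(c * 9, (f, c, 3, 3))
        params[f"enc{i}_b1"] = np.zeros(f)
        params[f"enc{i}_w2"] = he(f * 9, (f, f, 3, 3))
        params[f"enc{i}_b2"] = np.zeros(f)
        c = f
    for i in range(depth - 2, -1, -1):
        f = filts[i]
        params[f"dec{i}_w1"] = he(c * 9, (f, c, 3, 3))
        params[f"dec{i}_b1"] = np.zeros(f)
        params[f"dec{i}_w2"] = he(2 * f * 9, (f, 2 * f, 3, 3))
        params[f"dec{i}_b2"] = np.zeros(f)
        c = f
    params["head_w"] = he(c, (1, c, 1, 1))
    params["head_b"] = np.zeros(1)
    return params


def forward(params: Params, x: np.ndarray, depth: int,
            cache: dict | None = None) -> np.ndarray:
    """Forward pass; returns logits (N,1,H,W). Fills ``cache`` if given."""
    skips = []
    record = cache is not None
    if record:
        cache["x"] = x
        cache["acts"] = {}
    acts = cache["acts"] if record else None

    h = x
    for i in range(depth):
        z1 = conv2d(h, params[f"enc{i}_w1"], params[f"enc{i}_b1"])
        a1 = np.maximum(z1, 0.0)
        z2 = conv2d(a1, params[f"enc{i}_w2"], params[f"enc{i}_b2"])
        a2 = np.maximum(z2, 0.0)
        if record:
            acts[f"enc{i}"] = (h, z1, a1, z2, a2)
        if i < depth - 1:
            skips.append(a2)
            pooled, pmask = maxpool2(a2)
            if record:
                acts[f"pool{i}"] = pmask
            h = pooled
        else:
            h = a2
    for i in range(depth - 2, -1, -1):
        up = upsample2(h)
        z1 = conv2d(up, params[f"dec{i}_w1"], params[f"dec{i}_b1"])
        a1 = np.maximum(z1, 0.0)
        cat = np.concatenate([skips[i], a1], axis=1)
        z2 = conv2d(cat, params[f"dec{i}_w2"], params[f"dec{i}_b2"])
        a2 = np.maximum(z2, 0.0)
        if record:
            acts[f"dec{i}"] = (h, up, z1, a1, cat, z2, a2)
        h = a2
    logits = conv2d(h, params["head_w"], params["head_b"])
    if record:
        acts["head"] = h
    return logits


def backward(params: Params, cache: dict, dlogits: np.ndarray,
             depth: int) -> Params:
    """Backprop through :func:`forward`; returns gradients per parameter."""
    grads: Params = {}
    acts = cache["acts"]

    h_in = acts["head"]
    dh, grads["head_w"], grads["head_b"] = conv2d_backward(
        h_in, params["head_w"], dlogits
    )
    dskips: dict[int, np.ndarray] = {}
    for i in range(0, depth - 1):
        h, up, z1, a1, cat, z2, a2 = acts[f"dec{i}"]
        dz2 = dh * (z2 > 0)
        dcat, grads[f"dec{i}_w2"], grads[f"dec{i}_b2"] = conv2d_backward(
            cat, params[f"dec{i}_w2"], dz2
        )
        f = a1.shape[1]
        dskips[i] = dcat[:, :f]
        da1 = dcat[:, f:]
        dz1 = da1 * (z1 > 0)
        dup, grads[f"dec{i}_w1"], grads[f"dec{i}_b1"] = conv2d_backward(
            up, params[f"dec{i}_w1"], dz1
        )
        dh = upsample2_backward(dup)
    for i in range(depth - 1, -1, -1):
        h, z1, a1, z2, a2 = acts[f"enc{i}"]
        if i < depth - 1:
            da2 = maxpool2_backward(dh, acts[f"pool{i}"]) + dskips[i]
        else:
            da2 = dh
        dz2 = da2 * (z2 > 0)
        da1, grads[f"enc{i}_w2"], grads[f"enc{i}_b2"] = conv2d_backward(
            a1, params[f"enc{i}_w2"], dz2
        )
        dz1 = da1 * (z1 > 0)
        dh, grads[f"enc{i}_w1"], grads[f"enc{i}_b1"] = conv2d_backward(
            h, params[f"enc{i}_w1"], dz1
        )
    return grads


class Adam:
    """Standard Adam optimizer over a parameter dict."""

    def __init__(self, params: Params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
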