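"""A minimal seeded convolutional-network toolkit (numpy only).

Implements exactly what the two trainable stages need: same-padded 3x3/1x1
convolutions via im2col, ReLU, 2x2 average pooling, nearest-neighbour
2x upsampling, softmax cross-entropy and weighted mean-squared-error
losses, and Adam.  Everything is float32 and fully determined by the
integer seed used at initialization; no threading or global state.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "AvgPool2", "Upsample2", "Sequential", "Adam",
           "softmax_cross_entropy", "weighted_mse", "spatial_softmax_ce"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W) -> (N,H,W,C*k*k) patches with same zero padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, h, w, k, k), strides=(s[0], s[1], s[2], s[3], s[2], s[3]),
        writeable=False)
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, w, c * k * k)


class Layer:
    params: list = []
    grads: list = []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded convolution with odd kernel size."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.W = (rng.standard_normal((cout, cin, k, k)) *
                  np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k = k
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._shape = x.shape
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)                      # (N,H,W,C*k*k)
        self._cols = cols
        wmat = self.W.reshape(self.W.shape[0], -1)     # (Cout, C*k*k)
        out = cols @ wmat.T + self.b                   # (N,H,W,Cout)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout):
        n, cout, h, w = dout.shape
        d = dout.transpose(0, 2, 3, 1).reshape(-1, cout)          # (NHW, Cout)
        cols = self._cols.reshape(-1, self._cols.shape[-1])       # (NHW, Ckk)
        self.grads[0][...] = (d.T @ cols).reshape(self.W.shape)
        self.grads[1][...] = d.sum(axis=0)
        # dx: correlate dout with flipped, channel-transposed kernels
        Wt = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)       # (Cin,Cout,k,k)
        cols_d = _im2col(np.ascontiguousarray(dout), self.k)      # (N,H,W,Cout*k*k)
        dx = cols_d @ Wt.reshape(Wt.shape[0], -1).T               # (N,H,W,Cin)
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class AvgPool2(Layer):
    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout):
        n, c, h, w = self._shape
        return (np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0)


class Upsample2(Layer):
    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


class Adam:
    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          class_weights: np.ndarray | None = None):
    """Per-pixel softmax cross-entropy with optional class weights.

    ``logits``: (N, C, H, W); ``labels``: (N, H, W) integer classes.
    ``class_weights`` (length C) rebalances rare structures (e.g. the
    talus covers ~1% of pixels).  Returns (loss, dlogits).
    """
    n, c, h, w = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    idx_n, idx_h, idx_w = np.meshgrid(np.arange(n), np.arange(h), np.arange(w),
                                      indexing="ij")
    picked = probs[idx_n, labels, idx_h, idx_w]
    if class_weights is None:
        pix_w = np.ones((n, h, w))
    else:
        pix_w = np.asarray(class_weights, float)[labels]
    norm = pix_w.sum()
    loss = float(-(pix_w * np.log(np.clip(picked, 1e-12, None))).sum() / norm)
    dlogits = probs * pix_w[:, None, :, :]
    dlogits[idx_n, labels, idx_h, idx_w] -= pix_w
    dlogits /= norm
    return loss, dlogits.astype(np.float32)


def weighted_mse(pred: np.ndarray, target: np.ndarray, pos_weight: float = 50.0):
    """MSE with extra weight on positive target mass (heatmap peaks).

    Averaged over batch and pixels but summed over channels, so the
    per-channel gradient scale does not shrink as landmark count grows.
    """
    n, c, h, w_ = pred.shape
    w = 1.0 + pos_weight * target
    diff = pred - target
    norm = n * h * w_
    loss = float((w * diff * diff).sum() / norm)
    dpred = (2.0 * w * diff / norm).astype(np.float32)
    return loss, dpred


def spatial_softmax_ce(logits: np.ndarray, target: np.ndarray):
    """Per-channel spatial cross-entropy for heatmap regression.

    Each channel's logits are softmax-normalized over its pixels and
    scored against the (mass-normalized) Gaussian target map; stray
    secondary modes are penalized directly, which plain MSE tolerates.
    Returns (loss, dlogits); the returned probabilities' scale is handled
    by the caller at decode time.
    """
    n, c, h, w = logits.shape
    flat = logits.reshape(n, c, h * w)
    z = flat - flat.max(axis=2, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=2, keepdims=True)
    t = target.reshape(n, c, h * w)
    tsum = t.sum(axis=2, keepdims=True)
    t = np.divide(t, tsum, out=np.zeros_like(t), where=tsum > 0)
    loss = float(-(t * np.log(np.clip(p, 1e-12, None))).sum() / n)
    dlogits = ((p - t) / n).reshape(n, c, h, w).astype(np.float32)
    # channels with empty targets (missing landmarks) contribute nothing
    empty = (tsum == 0).reshape(n, c)
    if empty.any():
        dlogits[empty] = 0.0
    return loss, dlogits
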