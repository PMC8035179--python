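"""Minimal CPU neural-network layers for the 3D U-Net.

Convolutions are im2col + BLAS matmul in float32; gradients are written
by hand and verified against finite differences in the test suite.
Arrays are channel-first: ``(C, D, H, W)``.  Only what the segmentation
network needs is implemented: 3D convolution (kernel 1 or 3, stride 1,
'same' padding), ReLU, per-channel instance normalization, 2x average
pooling, 2x nearest-neighbour upsampling, channel concatenation, and a
softmax soft-Dice loss.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


# ---------------------------------------------------------------------------
# im2col 3D convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, D, H, W) -> (C*k^3, N) patch matrix, 'same' padding.

    Row order matches ``weight.reshape(cout, cin*k^3)``: channel-major,
    then kernel offset.  Built by k^3 contiguous slice copies (fast on
    one core) rather than a strided window gather.
    """
    c, d, h, w = x.shape
    n = d * h * w
    if k == 1:
        return x.reshape(c, n)
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    buf = np.empty((c, k * k * k, n), dtype=x.dtype)
    o = 0
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                buf[:, o, :] = xp[:, dz : dz + d, dy : dy + h, dx : dx + w].reshape(c, n)
                o += 1
    return buf.reshape(c * k * k * k, n)


def conv3d_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """weight: (cout, cin, k, k, k); bias: (cout,)."""
    cout, cin, k, _, _ = weight.shape
    _, d, h, w = x.shape
    cols = _im2col(x, k)
    y = weight.reshape(cout, -1) @ cols
    y += bias[:, None]
    return y.reshape(cout, d, h, w)


# ---------------------------------------------------------------------------
# Layers (forward caches what backward needs)
# ---------------------------------------------------------------------------

class Conv3d:
    """'same'-padded stride-1 convolution, kernel 1 or 3.

    The im2col patch matrix from the forward pass is kept until backward
    (memory for speed); ``is_input_layer`` skips the unneeded gradient
    w.r.t. the network input.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 is_input_layer: bool = False):
        fan_in = cin * k ** 3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k, k)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.k = k
        self.is_input_layer = is_input_layer
        self._cols = None
        self._shape = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        cout = self.w.shape[0]
        self._shape = x.shape
        self._cols = _im2col(x, self.k)
        y = self.w.reshape(cout, -1) @ self._cols
        y += self.b[:, None]
        return y.reshape((cout,) + x.shape[1:])

    def backward(self, dy):
        cout, cin = self.w.shape[:2]
        dy_mat = dy.reshape(cout, -1)  # (cout, N)
        dw = (dy_mat @ self._cols.T).reshape(self.w.shape).astype(F32)
        self._cols = None
        db = dy.sum(axis=(1, 2, 3)).astype(F32)
        if self.is_input_layer:
            return None, [dw, db]
        wt = np.ascontiguousarray(
            self.w.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        )
        dx = conv3d_forward(dy, wt, np.zeros(cin, dtype=F32))
        return dx, [dw, db]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, F32(0))

    def backward(self, dy):
        dx = np.where(self._mask, dy, F32(0))
        self._mask = None
        return dx, []


class InstanceNorm:
    """Per-channel normalization over the spatial dimensions."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.g = np.ones(c, dtype=F32)
        self.b = np.zeros(c, dtype=F32)
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.g, self.b]

    def forward(self, x):
        c = x.shape[0]
        flat = x.reshape(c, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((flat - mu) * inv).astype(F32)
        self._cache = (xhat, inv.astype(F32))
        y = xhat * self.g[:, None] + self.b[:, None]
        return y.reshape(x.shape)

    def backward(self, dy):
        xhat, inv = self._cache
        self._cache = None
        c = dy.shape[0]
        dyf = dy.reshape(c, -1)
        dg = (dyf * xhat).sum(axis=1).astype(F32)
        db = dyf.sum(axis=1).astype(F32)
        dxhat = dyf * self.g[:, None]
        n = xhat.shape[1]
        dx = inv * (
            dxhat
            - dxhat.mean(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
        )
        return dx.astype(F32).reshape(dy.shape), [dg, db]


class AvgPool2:
    def params(self):
        return []

    def forward(self, x):
        c, d, h, w = x.shape
        self._shape = x.shape
        return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))

    def backward(self, dy):
        c, d, h, w = self._shape
        dx = np.repeat(np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2), 2, axis=3) / F32(8)
        return dx.astype(F32), []


class Upsample2:
    def params(self):
        return []

    def forward(self, x):
        return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)

    def backward(self, dy):
        c, d, h, w = dy.shape
        dx = dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))
        return dx.astype(F32), []


# ---------------------------------------------------------------------------
# Softmax + soft multi-class Dice loss
# ---------------------------------------------------------------------------

def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z, dtype=np.float64)
    return (e / e.sum(axis=0, keepdims=True)).astype(F32)


def soft_dice_loss(
    logits: np.ndarray,
    target: np.ndarray,
    class_weights: np.ndarray,
    eps: float = 1.0,
    ce_weight: float = 0.0,
):
    """Soft multi-class Dice loss (optionally + cross-entropy) and gradient.

    ``target`` is an integer class map with the spatial shape of the
    logits.  Loss = 1 - weighted mean over classes of the soft Dice
    coefficient, plus ``ce_weight`` times the mean voxel cross-entropy
    (the dense term substantially accelerates early training).
    Returns (loss, dlogits, per_class_soft_dice).
    """
    k = logits.shape[0]
    p = softmax_channels(logits).reshape(k, -1).astype(np.float64)
    n = p.shape[1]
    t = np.zeros_like(p)
    t[target.reshape(-1), np.arange(n)] = 1.0
    w = np.asarray(class_weights, dtype=np.float64)
    inter = (p * t).sum(axis=1)
    denom = p.sum(axis=1) + t.sum(axis=1) + eps
    dice_c = (2.0 * inter + eps) / denom
    loss = 1.0 - float((w * dice_c).sum() / w.sum())
    # d(dice_c)/dp_c[i] = (2 t_c[i] * denom_c - (2 inter_c + eps)) / denom_c^2
    dp = -(w / w.sum())[:, None] * (
        (2.0 * t * denom[:, None] - (2.0 * inter + eps)[:, None]) / (denom ** 2)[:, None]
    )
    # softmax backward for the dice term
    dz = p * (dp - (p * dp).sum(axis=0, keepdims=True))
    if ce_weight:
        pt = p[target.reshape(-1), np.arange(n)]
        loss += ce_weight * float(-np.log(np.clip(pt, 1e-12, None)).mean())
        dz += ce_weight * (p - t) / n
    return loss, dz.astype(F32).reshape(logits.shape), dice_c


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g64 = g.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g64
            v *= self.b2
            v += (1 - self.b2) * g64 * g64
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
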