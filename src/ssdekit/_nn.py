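"""Minimal NumPy CNN primitives for the segmentation U-Net.

Implements exactly the layers the encoder-decoder needs — 2-D convolution
(im2col + matmul), ReLU, 2x2 max pooling, 2x nearest-neighbour upsampling,
residual blocks and a fused softmax / cross-entropy head — with hand-written
backward passes and an Adam optimiser.  Everything is plain float32 NumPy,
so training is bit-for-bit reproducible for a fixed seed.

Tensors are laid out ``(N, C, H, W)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2", "Upsample2", "ResBlock", "Adam",
           "softmax", "softmax_cross_entropy"]


class Conv2D:
    """k x k same-padding convolution; He-initialised."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int, k: int = 3):
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        p = k // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (c*k*k, n*h*w)
        return win.transpose(1, 4, 5, 0, 2, 3).reshape(c * k * k, n * h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = np.ascontiguousarray(self._im2col(x))
        self._cols, self._shape = cols, x.shape
        y = self.W @ cols + self.b[:, None]
        return y.reshape(self.cout, n, h, w).transpose(1, 0, 2, 3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        k, p = self.k, self.k // 2
        dyf = dy.transpose(1, 0, 2, 3).reshape(self.cout, n * h * w)
        self.gW += dyf @ self._cols.T
        self.gb += dyf.sum(axis=1)
        dcols = (self.W.T @ dyf).reshape(c, k, k, n, h, w)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, i, j].transpose(1, 0, 2, 3)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2:
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class Upsample2:
    """2x nearest-neighbour upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ResBlock:
    """Two 3x3 convolutions with an identity (or 1x1-projected) shortcut."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int):
        self.conv1 = Conv2D(rng, cin, cout, 3)
        self.conv2 = Conv2D(rng, cout, cout, 3)
        self.proj = Conv2D(rng, cin, cout, 1) if cin != cout else None
        self.relu1 = ReLU()
        self.relu2 = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        s = self.proj.forward(x) if self.proj is not None else x
        return self.relu2.forward(h + s)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dy)
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        dx += self.proj.backward(d) if self.proj is not None else d
        return dx

    def params(self):
        out = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params  # list of (value, grad) array pairs
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0


def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel-wise softmax over (N, C, H, W) logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean per-pixel cross entropy and its gradient w.r.t. the logits.

    labels: (N, H, W) integer class ids.
    """
    p = softmax(logits)
    n, c, h, w = logits.shape
    idx = (np.arange(n)[:, None, None], labels, np.arange(h)[None, :, None],
           np.arange(w)[None, None, :])
    picked = p[idx[0], idx[1], idx[2], idx[3]]
    loss = float(-np.log(np.maximum(picked, 1e-12)).mean())
    grad = p.copy()
    grad[idx[0], idx[1], idx[2], idx[3]] -= 1.0
    grad /= n * h * w
    return loss, grad.astype(np.float32)
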