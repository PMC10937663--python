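"""Convolutional network primitives in numpy with explicit backpropagation.

Layers operate on float32 batches shaped ``(N, C, H, W)``.  Each layer
implements ``forward(x)`` (caching what its backward pass needs) and
``backward(dy)`` (accumulating parameter gradients and returning the input
gradient).  Convolutions use an im2col layout so the inner loop is a single
BLAS matrix product; the column tensor is rebuilt from / scattered back to
the padded input with nine strided slice operations, which keeps both
directions vectorized.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "UpConv2",
    "Adam",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d:
    """k x k convolution with 'same' zero padding (odd k), stride 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("same-padding convolution needs an odd kernel")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.weight = Param(_he(rng, (out_ch, in_ch, kernel, kernel), in_ch * kernel**2))
        self.bias = Param(np.zeros(out_ch, dtype=np.float32))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _im2col(self, xp: np.ndarray, h: int, w: int) -> np.ndarray:
        n, c = xp.shape[:2]
        k = self.k
        patches = [xp[:, :, i : i + h, j : j + w] for i in range(k) for j in range(k)]
        cols = np.stack(patches, axis=1)            # (N, k*k, C, H, W)
        return cols.reshape(n, k * k * c, h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = self._im2col(xp, h, w)
        self._cols, self._shape = cols, x.shape
        # weight reordered to match the (k*k, C) column layout
        w2 = self.weight.value.transpose(0, 2, 3, 1).reshape(self.out_ch, -1)
        y = np.matmul(w2[None], cols) + self.bias.value[None, :, None]
        return y.reshape(n, self.out_ch, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        k, p = self.k, self.k // 2
        dym = dy.reshape(n, self.out_ch, h * w)
        dw2 = np.tensordot(dym, self._cols, axes=([0, 2], [0, 2]))
        self.weight.grad += (
            dw2.reshape(self.out_ch, k, k, self.in_ch).transpose(0, 3, 1, 2)
        )
        self.bias.grad += dym.sum(axis=(0, 2))
        w2 = self.weight.value.transpose(0, 2, 3, 1).reshape(self.out_ch, -1)
        dcols = np.matmul(w2.T[None], dym).reshape(n, k * k, self.in_ch, h, w)
        dxp = np.zeros((n, self.in_ch, h + 2 * p, w + 2 * p), dtype=np.float32)
        idx = 0
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, idx]
                idx += 1
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, np.float32(0.0))


class MaxPool2:
    """2 x 2 max pooling, stride 2 (even spatial dims required)."""

    params: list[Param] = []

    def __init__(self):
        self._arg: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("max pooling needs even spatial dimensions")
        xb = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xb = xb.reshape(n, c, h // 2, w // 2, 4)
        self._arg = np.argmax(xb, axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xb, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        db = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(db, self._arg[..., None], dy[..., None], axis=-1)
        db = db.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return db.reshape(n, c, h, w)


class UpConv2:
    """2 x 2 transposed convolution with stride 2 (doubles H and W)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Param(_he(rng, (in_ch, out_ch, 2, 2), in_ch))
        self.bias = Param(np.zeros(out_ch, dtype=np.float32))
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        yb = np.einsum("nchw,ckab->nkhawb", x, self.weight.value, optimize=True)
        y = yb.reshape(n, self.out_ch, 2 * h, 2 * w)
        return y + self.bias.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, k, h2, w2 = dy.shape
        h, w = h2 // 2, w2 // 2
        dyb = dy.reshape(n, k, h, 2, w, 2)
        self.weight.grad += np.einsum(
            "nchw,nkhawb->ckab", self._x, dyb, optimize=True
        )
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("nkhawb,ckab->nchw", dyb, self.weight.value, optimize=True)
        self._x = None
        return dx.astype(np.float32)


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
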