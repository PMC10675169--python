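"""Minimal CPU neural-network engine: 2-D convolutions, residual blocks,
pooling, a dense head, backprop and Adam.

Only what the frame classifier needs is implemented.  Convolutions are
stride-1 with 'same' zero padding, realised as an im2col matrix product;
downsampling is 2x2 average pooling (floor-cropped on odd dimensions).
Every layer caches what its backward pass needs; there is no autograd.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base layer: forward(x) -> y, backward(dy) -> dx, trainable params."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv2D(Layer):
    """Stride-1 'same' 2-D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.pad = kernel // 2
        fan_in = c_in * kernel * kernel
        self.w = _he_normal(rng, (fan_in, c_out), fan_in)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # win: (b, c, h, w, k, k) -> (b*h*w, c*k*k)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        cols = self._im2col(x)
        if train:
            self._cols, self._shape = cols, x.shape
        y = cols @ self.w + self.b
        return y.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._shape is not None
        b, c, h, w = self._shape
        k = self.k
        dflat = dy.transpose(0, 2, 3, 1).reshape(b * h * w, self.c_out)
        self.grads[0][...] = self._cols.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        # input gradient = same-padded correlation of dy with the spatially
        # flipped kernel, channels transposed (valid for odd k)
        w_back = (
            self.w.reshape(c, k, k, self.c_out)[:, ::-1, ::-1, :]
            .transpose(3, 1, 2, 0)
            .reshape(self.c_out * k * k, c)
        )
        cols_dy = self._im2col(np.ascontiguousarray(dy))
        dx = (cols_dy @ np.ascontiguousarray(w_back)).reshape(b, h, w, c)
        self._cols = None
        return dx.transpose(0, 3, 1, 2)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return dy * self._mask


class AvgPool2(Layer):
    """2x2 average pooling; odd trailing rows/columns are dropped."""

    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        if train:
            self._shape = x.shape
        return x[:, :, : h2 * 2, : w2 * 2].reshape(b, c, h2, 2, w2, 2).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._shape is not None
        b, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros(self._shape, dtype=dy.dtype)
        up = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0
        dx[:, :, : h2 * 2, : w2 * 2] = up
        return dx


class GlobalAvgPool(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._hw: tuple[int, int] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._hw is not None
        h, w = self._hw
        return np.broadcast_to(dy[:, :, None, None] / (h * w), dy.shape + (h, w)).copy()


class Dropout(Layer):
    """Inverted dropout; identity when rate is 0 or at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(DTYPE)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.w = _he_normal(rng, (c_in, c_out), c_in)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


class ResidualBlock(Layer):
    """VGG-style double 3x3 convolution with an identity (or 1x1-projected)
    skip connection: y = relu(conv2(relu(conv1(x))) + proj(x))."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv1 = Conv2D(c_in, c_out, kernel, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(c_out, c_out, kernel, rng)
        self.proj = Conv2D(c_in, c_out, 1, rng) if c_in != c_out else None
        self.relu_out = ReLU()
        children = [self.conv1, self.conv2] + ([self.proj] if self.proj else [])
        self.params = [p for c in children for p in c.params]
        self.grads = [g for c in children for g in c.grads]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.relu1.forward(self.conv1.forward(x, train), train)
        y = self.conv2.forward(h, train)
        skip = self.proj.forward(x, train) if self.proj else x
        return self.relu_out.forward(y + skip, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dy)
        dx_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        dx_skip = self.proj.backward(d) if self.proj else d
        return dx_main + dx_skip


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers
        self.params = [p for l in layers for p in l.params]
        self.grads = [g for l in layers for g in l.grads]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adaptive-moment optimizer over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                    label_mask: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Mean per-label binary cross-entropy and its gradient w.r.t. logits.

    ``label_mask`` (8,) excludes untrainable labels from loss and gradient.
    """
    z, y = logits, targets.astype(DTYPE)
    # numerically stable: max(z,0) - z*y + log(1 + exp(-|z|))
    losses = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = sigmoid(z) - y
    if label_mask is not None:
        losses = losses * label_mask
        grad = grad * label_mask
        denom = z.shape[0] * max(int(label_mask.sum()), 1)
    else:
        denom = z.size
    return float(losses.sum() / denom), grad / denom
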