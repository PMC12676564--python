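"""Building blocks of the self-contained numpy 3D CNN.

All layers implement ``forward(x, train)`` / ``backward(dout)`` and expose
``params`` / ``grads`` dicts for the optimizer.  Arrays are float32 and laid
out ``(N, C, D, H, W)``.  Convolution is im2col + matmul; its backward folds
the column gradient back with 27 vectorized slice-adds.  Max pooling is
2x2x2, stride 2, ceil mode (odd extents padded with -inf), which is what
turns 50 -> 25 -> 13 -> 7 and 12 -> 6 -> 3 -> 2 in the reference network.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3D(Layer):
    """3x3x3 convolution, stride 1, same padding (He-initialized)."""

    def __init__(self, in_ch, out_ch, kernel=3, rng=None):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel ** 3
        self.params["W"] = (rng.standard_normal((out_ch, fan_in))
                            * np.sqrt(2.0 / fan_in)).astype(F32)
        self.params["b"] = np.zeros(out_ch, dtype=F32)

    def forward(self, x, train=False):
        k, p = self.k, self.k // 2
        n, c, d, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        # column buffer (n, c*k^3, d*h*w) filled by k^3 contiguous block copies;
        # row index is c * k^3 + (kd*k + kh)*k + kw, matching the W layout
        cols = np.empty((n, c * k ** 3, d * h * w), dtype=F32)
        cols5 = cols.reshape(n, c, k ** 3, d, h, w)
        for j, (kd, kh, kw) in enumerate(np.ndindex(k, k, k)):
            cols5[:, :, j] = xp[:, :, kd:kd + d, kh:kh + h, kw:kw + w]
        out = np.matmul(self.params["W"][None], cols)  # (n, out_ch, d*h*w)
        out += self.params["b"][None, :, None]
        self._cache = (cols, x.shape)
        return out.reshape(n, self.out_ch, d, h, w)

    def backward(self, dout):
        cols, xshape = self._cache
        n, c, d, h, w = xshape
        k, p = self.k, self.k // 2
        dout3 = dout.reshape(n, self.out_ch, d * h * w)
        self.grads["W"] = np.matmul(dout3, cols.transpose(0, 2, 1)).sum(axis=0)
        self.grads["b"] = dout3.sum(axis=(0, 2))
        dcols = np.matmul(self.params["W"].T[None], dout3)
        dcols5 = dcols.reshape(n, c, k ** 3, d, h, w)
        dxp = np.zeros((n, c, d + 2 * p, h + 2 * p, w + 2 * p), dtype=F32)
        for j, (kd, kh, kw) in enumerate(np.ndindex(k, k, k)):
            dxp[:, :, kd:kd + d, kh:kh + h, kw:kw + w] += dcols5[:, :, j]
        self._cache = None
        return dxp[:, :, p:p + d, p:p + h, p:p + w]


class BatchNorm(Layer):
    """Per-feature-map batch normalization over (N, D, H, W)."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=F32)
        self.params["beta"] = np.zeros(channels, dtype=F32)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def forward(self, x, train=False):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(F32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1, 1)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.params["gamma"].reshape(shape) * xhat \
            + self.params["beta"].reshape(shape)

    def backward(self, dout):
        xhat, inv, xshape = self._cache
        axes = (0, 2, 3, 4)
        m = dout.size / dout.shape[1]
        shape = (1, -1, 1, 1, 1)
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"].reshape(shape)
        dx = (inv.reshape(shape) / m) * (
            m * dxhat
            - dxhat.sum(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape))
        self._cache = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        out = dout * self._mask
        self._mask = None
        return out


class MaxPool3D(Layer):
    """2x2x2 max pooling, stride 2, ceil mode (-inf padding on odd extents)."""

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        pd, ph, pw = d % 2, h % 2, w % 2
        self._inshape = x.shape
        if pd or ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, pd), (0, ph), (0, pw)),
                       constant_values=-np.inf)
        n, c, d2, h2, w2 = x.shape
        blocks = x.reshape(n, c, d2 // 2, 2, h2 // 2, 2, w2 // 2, 2)
        blocks = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, d2 // 2, h2 // 2, w2 // 2, 8)
        self._arg = blocks.argmax(axis=-1)
        return np.ascontiguousarray(blocks.max(axis=-1))

    def backward(self, dout):
        n, c, d, h, w = self._inshape
        d2, h2, w2 = d + d % 2, h + h % 2, w + w % 2
        od, oh, ow = d2 // 2, h2 // 2, w2 // 2
        dblocks = np.zeros((n, c, od, oh, ow, 8), dtype=F32)
        np.put_along_axis(dblocks, self._arg[..., None], dout[..., None], axis=-1)
        dxp = dblocks.reshape(n, c, od, oh, ow, 2, 2, 2).transpose(
            0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d2, h2, w2)
        self._arg = None
        return np.ascontiguousarray(dxp[:, :, :d, :h, :w])


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p, rng):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(F32) / (1 - self.p)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        out = dout * self._mask
        self._mask = None
        return out


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = (rng.standard_normal((n_in, n_out))
                            * np.sqrt(2.0 / n_in)).astype(F32)
        self.params["b"] = np.zeros(n_out, dtype=F32)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.params["W"].T
        self._x = None
        return dx


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits, y):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = -np.log(probs[np.arange(n), y] + 1e-12).mean()
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(F32)


class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, layers, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, layer in enumerate(self.layers):
            for key, p in layer.params.items():
                g = layer.grads[key].astype(F32)
                self.m[i][key] = self.b1 * self.m[i][key] + (1 - self.b1) * g
                self.v[i][key] = self.b2 * self.v[i][key] + (1 - self.b2) * g * g
                mhat = self.m[i][key] / b1t
                vhat = self.v[i][key] / b2t
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)
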