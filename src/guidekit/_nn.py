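"""Minimal numpy feed-forward engine: the layers needed by the guide-activity networks.

Implements 1-D convolution (length-preserving), max/average pooling, batch
normalization, upsampling, dense layers, ReLU, Adam, and the two losses used
for training (MSE for regression, binary cross-entropy on logits for
reconstruction/classification).  Forward passes cache what backward needs;
gradients are exact and verified against finite differences in the test suite.

All randomness flows through an explicit ``numpy.random.Generator``.  Weights
use Glorot-uniform initialization; L2 weight decay is applied to convolution
and dense weight matrices only (not biases, not batch-norm parameters).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D", "ReLU", "MaxPool1D", "AvgPool1D", "BatchNorm1D", "UpSample1D",
    "Flatten", "Dense", "Sequential", "Adam",
    "mse_loss", "bce_with_logits_loss", "sigmoid", "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class: parameters live in ``self.params`` (name -> array), gradients
    in ``self.grads`` with matching keys.  ``decay`` lists param names subject
    to L2."""

    decay: tuple = ()

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=True):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv1D(Layer):
    """Length-preserving 1-D convolution over (batch, channels, length) input.

    Odd kernel with symmetric zero padding keeps the output length equal to
    the input length, so pooling alone controls the n -> n/2 -> n/4 arithmetic.
    """

    decay = ("W",)

    def __init__(self, in_ch, out_ch, kernel=5, rng=None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd for symmetric same-padding")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        rng = rng or np.random.default_rng()
        fan_in, fan_out = in_ch * kernel, out_ch * kernel
        self.params["W"] = glorot_uniform(rng, (out_ch, in_ch, kernel), fan_in, fan_out)
        self.params["b"] = np.zeros(out_ch)

    def forward(self, x, train=True):
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # cols: (B, C, L, k) sliding windows
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        self._cols = cols
        self._in_len = x.shape[2]
        out = np.einsum("bclk,ock->bol", cols, self.params["W"], optimize=True)
        out += self.params["b"][None, :, None]
        return out

    def backward(self, dout):
        W = self.params["W"]
        self.grads["W"] = np.einsum("bclk,bol->ock", self._cols, dout, optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2))
        dcols = np.einsum("bol,ock->bclk", dout, W, optimize=True)
        B, C, L, k = dcols.shape
        pad = self.kernel // 2
        dxp = np.zeros((B, C, L + 2 * pad))
        for j in range(k):
            dxp[:, :, j:j + L] += dcols[:, :, :, j]
        return dxp[:, :, pad:pad + self._in_len]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; trailing bases beyond a full window are
    dropped (floor division), matching the documented ⌊n/4⌋ feature-map law."""

    def __init__(self, size=2):
        super().__init__()
        self.size = size

    def forward(self, x, train=True):
        B, C, L = x.shape
        Lo = L // self.size
        xr = x[:, :, :Lo * self.size].reshape(B, C, Lo, self.size)
        self._argmax = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dout):
        B, C, Lo = dout.shape
        dxr = np.zeros((B, C, Lo, self.size))
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=3)
        dx = np.zeros(self._in_shape)
        dx[:, :, :Lo * self.size] = dxr.reshape(B, C, Lo * self.size)
        return dx


class AvgPool1D(Layer):
    def __init__(self, size=2):
        super().__init__()
        self.size = size

    def forward(self, x, train=True):
        B, C, L = x.shape
        Lo = L // self.size
        self._in_shape = x.shape
        return x[:, :, :Lo * self.size].reshape(B, C, Lo, self.size).mean(axis=3)

    def backward(self, dout):
        B, C, Lo = dout.shape
        dx = np.zeros(self._in_shape)
        dx[:, :, :Lo * self.size] = np.repeat(dout / self.size, self.size, axis=2)
        return dx


class UpSample1D(Layer):
    def __init__(self, size=2):
        super().__init__()
        self.size = size

    def forward(self, x, train=True):
        return np.repeat(x, self.size, axis=2)

    def backward(self, dout):
        B, C, L = dout.shape
        return dout.reshape(B, C, L // self.size, self.size).sum(axis=3)


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length); running statistics
    (momentum 0.9) are used at inference."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        return self.params["gamma"][None, :, None] * self._xhat + self.params["beta"][None, :, None]

    def backward(self, dout):
        g = self.params["gamma"]
        xhat, std = self._xhat, self._std
        m = dout.shape[0] * dout.shape[2]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dout.sum(axis=(0, 2))
        dxhat = dout * g[None, :, None]
        dx = (dxhat - dxhat.mean(axis=(0, 2), keepdims=True)
              - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / m) / std[None, :, None]
        return dx


class Flatten(Layer):
    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Dense(Layer):
    decay = ("W",)

    def __init__(self, in_dim, out_dim, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim)
        self.params["b"] = np.zeros(out_dim)

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential:
    """A plain layer stack with forward/backward and weight (de)serialization."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def get_weights(self):
        out = []
        for layer in self.layers:
            d = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, BatchNorm1D):
                d["running_mean"] = layer.running_mean.copy()
                d["running_var"] = layer.running_var.copy()
            out.append(d)
        return out

    def set_weights(self, weights):
        if len(weights) != len(self.layers):
            raise ValueError(f"expected {len(self.layers)} layer states, got {len(weights)}")
        for layer, d in zip(self.layers, weights):
            for k in layer.params:
                if layer.params[k].shape != d[k].shape:
                    raise ValueError(f"shape mismatch for {k}: "
                                     f"{layer.params[k].shape} vs {d[k].shape}")
                layer.params[k] = d[k].copy()
            if isinstance(layer, BatchNorm1D):
                layer.running_mean = d["running_mean"].copy()
                layer.running_var = d["running_var"].copy()


class Adam:
    """Adam over a set of layers, with optional L2 decay on flagged weights."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, l2=0.0):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                if self.l2 and k in layer.decay:
                    g = g + self.l2 * p
                m = self._m[i][k] = self.b1 * self._m[i][k] + (1 - self.b1) * g
                v = self._v[i][k] = self.b2 * self._v[i][k] + (1 - self.b2) * g * g
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred, target):
    """Mean squared error and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    grad = 2.0 * diff / diff.size
    return loss, grad

def bce_with_logits_loss(logits, target):
    """Numerically stable elementwise binary cross-entropy on raw logits."""
    loss = float(np.mean(np.maximum(logits, 0) - logits * target
                         + np.log1p(np.exp(-np.abs(logits)))))
    grad = (sigmoid(logits) - target) / logits.size
    return loss, grad
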