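"""Minimal NumPy neural-network layers used by the texture model.

Implements exactly what the prediction network needs: 2-D convolution
(stride 1, zero padding), 2x2 max pooling, dense layers, ReLU, inverted
dropout, and stochastic gradient descent with classical momentum.  Arrays are
NHWC.  Every layer caches what its backward pass needs; ``backward`` returns
the gradient with respect to the input and stores parameter gradients on the
layer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    trainable = True

    def params(self):
        return {}

    def grads(self):
        return {}

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk) convolution, stride 1, 'same' zero padding, NHWC."""

    def __init__(self, in_ch, out_ch, ksize=3, rng=None):
        rng = rng or np.random.default_rng()
        fan_in = ksize * ksize * in_ch
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (ksize, ksize, in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.ksize = ksize
        self.pad = ksize // 2
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.gW, "b": self.gb}

    def forward(self, x, train=False, rng=None):
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # patches: (N, H, W, k, k, C)
        patches = sliding_window_view(xp, (self.ksize, self.ksize), axis=(1, 2))
        patches = np.moveaxis(patches, 3, 5)  # (N,H,W,k,k,C)
        self._patches = patches
        self._xshape = x.shape
        return np.einsum("nhwklc,klco->nhwo", patches, self.W, optimize=True) + self.b

    def backward(self, grad):
        self.gW = np.einsum("nhwklc,nhwo->klco", self._patches, grad, optimize=True)
        self.gb = grad.sum(axis=(0, 1, 2))
        n, h, w, _ = self._xshape
        p, k = self.pad, self.ksize
        gxp = np.zeros((n, h + 2 * p, w + 2 * p, self.W.shape[2]))
        contrib = np.einsum("nhwo,klco->nhwklc", grad, self.W, optimize=True)
        for i in range(k):
            for j in range(k):
                gxp[:, i:i + h, j:j + w, :] += contrib[:, :, :, i, j, :]
        return gxp[:, p:p + h, p:p + w, :]


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2; input H, W must be even."""

    trainable = False

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = xr.reshape(n, h // 2, w // 2, 4, c)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, grad):
        n, h, w, c = self._shape
        g = np.zeros((n, h // 2, w // 2, 4, c))
        idx = np.indices(self._arg.shape)
        g[idx[0], idx[1], idx[2], self._arg, idx[3]] = grad
        g = g.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return g.reshape(n, h, w, c)


class ReLU(Layer):
    trainable = False

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    trainable = False

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.gW, "b": self.gb}

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(Layer):
    """Inverted dropout; active only when ``train`` and a rng is supplied."""

    trainable = False

    def __init__(self, rate):
        self.rate = float(rate)

    def forward(self, x, train=False, rng=None):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def param_list(self):
        """Flat [(layer, name, array), ...] over all trainable parameters."""
        out = []
        for layer in self.layers:
            for name, arr in layer.params().items():
                out.append((layer, name, arr))
        return out


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, param_list, lr, momentum=0.0):
        self.param_list = param_list
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.velocity = [np.zeros_like(arr) for _, _, arr in param_list]

    def step(self):
        for v, (layer, name, arr) in zip(self.velocity, self.param_list):
            g = layer.grads()[name]
            v *= self.momentum
            v -= self.lr * g
            arr += v
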