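"""Minimal 1D convolutional network engine (numpy, manual backprop).

Provides exactly what the RBC-flux regressor needs: same-padding Conv1d,
ReLU, max pooling, global average pooling, dense layers, residual adds and
an Adam optimizer with global-norm gradient clipping. Layers expose
``forward``/``backward``; parameters and gradients live in plain dicts so
the whole parameter vector can be flattened for finite-difference checks.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft


class Layer:
    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padding, stride-1 1D convolution on (B, C, L) arrays."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.kernel = kernel
        self.params = {
            "W": rng.normal(0.0, scale, (c_out, c_in, kernel)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=True):
        # FFT convolution: same-padding correlation y[b,o,l] =
        # sum_{c,k} W[o,c,k] x[b,c,l+k-pl]
        k = self.kernel
        pl = (k - 1) // 2
        b, c, l = x.shape
        n = sfft.next_fast_len(l + k - 1)
        self._shape_in = (b, c, l)
        self._n = n
        self._fx = sfft.rfft(x, n=n, axis=2)                  # B,C,F
        fw = sfft.rfft(self.params["W"][:, :, ::-1], n=n, axis=2)  # O,C,F
        y_full = sfft.irfft(np.einsum("bcf,ocf->bof", self._fx, fw,
                                      optimize=True), n=n, axis=2)
        off = k - 1 - pl
        return (y_full[:, :, off: off + l]
                + self.params["b"][None, :, None])

    def backward(self, dy):
        k = self.kernel
        pl = (k - 1) // 2
        b, c, l = self._shape_in
        n = self._n
        fdy = sfft.rfft(dy, n=n, axis=2)                      # B,O,F
        # dW[o,c,k'] = sum_{b,l} x[b,c,l+k'-pl] dy[b,o,l]: circular
        # cross-correlation of x with dy at lag k'-pl
        corr = sfft.irfft(np.einsum("bcf,bof->ocf", self._fx,
                                    np.conj(fdy), optimize=True),
                          n=n, axis=2)
        lags = (np.arange(k) - pl) % n
        self.grads["W"][...] = corr[:, :, lags]
        self.grads["b"][...] = dy.sum(axis=(0, 2))
        # dx[b,c,j] = sum_{o,k'} W[o,c,k'] dy[b,o,j+pl-k'] =
        # (dy * W)[j+pl] (ordinary convolution)
        fw = sfft.rfft(self.params["W"], n=n, axis=2)
        dx_full = sfft.irfft(np.einsum("bof,ocf->bcf", fdy, fw,
                                       optimize=True), n=n, axis=2)
        return dx_full[:, :, pl: pl + l]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._m = x > 0
        return x * self._m

    def backward(self, dy):
        return dy * self._m


class MaxPool1d(Layer):
    """Same-padding, stride-1 max pooling (window 3)."""

    def __init__(self, window: int = 3):
        super().__init__()
        self.window = window

    def forward(self, x, train=True):
        k = self.window
        pl, pr = (k - 1) // 2, k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)),
                    constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        self._arg = win.argmax(axis=3)
        self._shape = x.shape
        self._pl = pl
        return win.max(axis=3)

    def backward(self, dy):
        b, c, l = self._shape
        dx = np.zeros((b, c, l + self.window - 1))
        src = self._arg + np.arange(l)[None, None, :]
        bi = np.arange(b)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(dx, (bi, ci, src), dy)
        return dx[:, :, self._pl: self._pl + l]


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._l = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None], self._l, axis=2) / self._l


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        super().__init__()
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"][...] = self._x.T @ dy
        self.grads["b"][...] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, layers, lr=8e-4, beta1=0.9, beta2=0.999, eps=1e-8,
                 grad_clip=500.0):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self):
        gnorm = np.sqrt(sum(float((l.grads[k] ** 2).sum())
                            for l in self.layers for k in l.grads))
        scale = 1.0
        if self.grad_clip and gnorm > self.grad_clip:
            scale = self.grad_clip / (gnorm + 1e-12)
        self.t += 1
        for i, l in enumerate(self.layers):
            for k in l.params:
                g = l.grads[k] * scale
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mh = self.m[i][k] / (1 - self.b1 ** self.t)
                vh = self.v[i][k] / (1 - self.b2 ** self.t)
                l.params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def get_flat_params(layers) -> np.ndarray:
    return np.concatenate([l.params[k].ravel()
                           for l in layers if l.params
                           for k in sorted(l.params)])


def set_flat_params(layers, flat: np.ndarray) -> None:
    i = 0
    for l in layers:
        if not l.params:
            continue
        for k in sorted(l.params):
            n = l.params[k].size
            l.params[k][...] = flat[i: i + n].reshape(l.params[k].shape)
            i += n


def get_flat_grads(layers) -> np.ndarray:
    return np.concatenate([l.grads[k].ravel()
                           for l in layers if l.params
                           for k in sorted(l.grads)])
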