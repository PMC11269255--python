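"""Minimal NumPy layers with hand-written backward passes, plus Adam.

These primitives exist to support a small fully-convolutional
encoder-decoder trained one sample at a time, so every layer operates on a
single ``(channels, height, width)`` array — there is no batch axis.
Forward passes cache exactly what their backward pass needs; calling
``backward`` before ``forward`` is a programming error.

All parameters and activations are float32.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    """Base layer: parameter-free and stateless unless overridden."""

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def buffers(self) -> dict:
        """Non-trainable state (e.g. running statistics)."""
        return {}

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Conv2d(Layer):
    """2D convolution, stride 1, 'same' zero padding, via im2col + BLAS.

    Weights use He-normal initialization (the layers feed ReLUs)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, rng=None):
        rng = rng if rng is not None else np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.w = (rng.standard_normal((out_ch, fan_in)) * std).astype(DTYPE)
        self.b = np.zeros(out_ch, DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.k = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"dw": self.dw, "db": self.db}

    def forward(self, x, training=False, rng=None):
        c, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (c, h, w, k, k)
        col = np.ascontiguousarray(win.transpose(1, 2, 0, 3, 4)).reshape(h * w, c * k * k)
        self._col = col
        self._in_shape = (c, h, w)
        y = col @ self.w.T + self.b
        return np.ascontiguousarray(y.reshape(h, w, self.out_ch).transpose(2, 0, 1))

    def backward(self, dy):
        c, h, w = self._in_shape
        k, p = self.k, self.k // 2
        dyf = dy.transpose(1, 2, 0).reshape(h * w, self.out_ch)
        self.dw[...] = dyf.T @ self._col
        self.db[...] = dyf.sum(axis=0)
        dcol = (dyf @ self.w).reshape(h, w, c, k, k).transpose(2, 3, 4, 0, 1)
        dxp = np.zeros((c, h + 2 * p, w + 2 * p), DTYPE)
        for i in range(k):  # scatter-add of the k*k shifted views (col2im)
            for j in range(k):
                dxp[:, i:i + h, j:j + w] += dcol[:, i, j]
        return dxp[:, p:p + h, p:p + w]


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class BatchNorm2d(Layer):
    """Per-channel normalization over the spatial axes of one sample.

    With a batch of one, the "batch" statistics are the spatial mean and
    variance of each channel map. Running statistics (exponential moving
    average, momentum 0.1) are used in evaluation mode."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(ch, DTYPE)
        self.beta = np.zeros(ch, DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, DTYPE)
        self.running_var = np.ones(ch, DTYPE)
        self.eps = eps
        self.momentum = momentum

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"dgamma": self.dgamma, "dbeta": self.dbeta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, training=False, rng=None):
        if training:
            mean = x.mean(axis=(1, 2))
            var = x.var(axis=(1, 2))
            self.running_mean[...] = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var[...] = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        self._xhat = xhat
        self._inv_std = inv_std
        self._training = training
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, dy):
        xhat, inv_std = self._xhat, self._inv_std
        n = xhat.shape[1] * xhat.shape[2]
        self.dgamma[...] = (dy * xhat).sum(axis=(1, 2))
        self.dbeta[...] = dy.sum(axis=(1, 2))
        dxhat = dy * self.gamma[:, None, None]
        if not self._training:
            return dxhat * inv_std[:, None, None]
        # training mode: mean/var depend on x
        t1 = dxhat.sum(axis=(1, 2), keepdims=True)
        t2 = (dxhat * xhat).sum(axis=(1, 2), keepdims=True)
        return (inv_std[:, None, None] / n) * (n * dxhat - t1 - xhat * t2)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Ties resolve to the first (raster-order)
    maximum, so the backward pass routes each gradient to one pixel."""

    def forward(self, x, training=False, rng=None):
        c, h, w = x.shape
        xr = x.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._in_shape = (c, h, w)
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        c, h, w = self._in_shape
        out = np.zeros((c, h // 2, w // 2, 4), DTYPE)
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=-1)
        return out.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h, w)


class ConvTranspose2d(Layer):
    """Transposed convolution, kernel 2x2, stride 2 (exact 2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng=None):
        rng = rng if rng is not None else np.random.default_rng()
        std = np.sqrt(2.0 / in_ch)
        self.w = (rng.standard_normal((in_ch, out_ch, 2, 2)) * std).astype(DTYPE)
        self.b = np.zeros(out_ch, DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.in_ch = in_ch
        self.out_ch = out_ch

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"dw": self.dw, "db": self.db}

    def forward(self, x, training=False, rng=None):
        self._x = x
        c, h, w = x.shape
        y = np.einsum("chw,cdab->dhawb", x, self.w, optimize=True)
        y = y.reshape(self.out_ch, 2 * h, 2 * w)
        return y + self.b[:, None, None]

    def backward(self, dy):
        x = self._x
        c, h, w = x.shape
        dyr = dy.reshape(self.out_ch, h, 2, w, 2)
        self.dw[...] = np.einsum("chw,dhawb->cdab", x, dyr, optimize=True)
        self.db[...] = dy.sum(axis=(1, 2))
        return np.einsum("dhawb,cdab->chw", dyr, self.w, optimize=True)


class Dropout(Layer):
    """Inverted dropout: active only in training mode, identity otherwise."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        rng = rng if rng is not None else np.random.default_rng()
        self._mask = (rng.random(x.shape) >= self.rate).astype(DTYPE) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def iter_layers(layer):
    """Depth-first iteration over leaf layers."""
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from iter_layers(sub)
    else:
        yield layer


class Adam:
    """Adam optimizer over the parameters of a list of layers.

    Gradients are read from each layer's ``grads()`` dict, matched to
    parameters by order (a layer's params and grads dicts are parallel).
    """

    def __init__(self, layers, lr: float, beta1: float = 0.9, beta2: float = 0.99,
                 eps: float = 1e-8):
        self.layers = [l for layer in layers for l in iter_layers(layer) if l.params()]
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(self.layers):
            ps = list(layer.params().items())
            gs = list(layer.grads().values())
            for (name, p), g in zip(ps, gs):
                key = (li, name)
                if key not in self._m:
                    self._m[key] = np.zeros_like(p)
                    self._v[key] = np.zeros_like(p)
                m, v = self._m[key], self._v[key]
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
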