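"""Minimal numpy neural-network core for the convolutional deep embedder.

Tensors are channels-last (NHWC): batch, height, width, channels.

Layers carry explicit forward/backward passes (im2col-style convolutions via
``sliding_window_view``); parameters are ``Param`` objects updated by an
Adam optimizer with decoupled weight decay.  Everything is deterministic
given the generator used for initialization.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Layer", "Conv2D", "Dense", "ReLU", "Flatten", "Reshape",
           "Upsample", "Sequential", "Adam", "softplus", "sigmoid"]


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """2-D convolution, NHWC (channels-last) layout, symmetric padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 stride: tuple[int, int] = (1, 1), pad: int | None = None,
                 rng: np.random.Generator | None = None, name: str = "conv",
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        k = kernel
        self.kernel = k
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.stride = stride
        self.pad = (k // 2 if pad is None else pad)
        fan_in = in_ch * k * k
        # weight layout (kh, kw, c_in, c_out) to match im2col column order
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, in_ch, out_ch))
        self.W = Param(w.astype(dtype), f"{name}.W")
        self.b = Param(np.zeros(out_ch, dtype=dtype), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        sh, sw = self.stride
        p = self.pad
        kh = kw = self.kernel
        c = self.in_ch
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        v = sliding_window_view(xp, (kh, kw), axis=(1, 2))[:, ::sh, ::sw]
        n, ho, wo = v.shape[:3]
        # v is (n, ho, wo, c, kh, kw) -> columns ordered (kh, kw, c)
        cols = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3)
                                    ).reshape(n * ho * wo, kh * kw * c)
        out = cols @ self.W.value.reshape(-1, self.out_ch) + self.b.value
        self._cache = (cols, xp.shape, x.shape, (n, ho, wo))
        return out.reshape(n, ho, wo, self.out_ch)

    def backward(self, dout):
        cols, xp_shape, x_shape, (n, ho, wo) = self._cache
        sh, sw = self.stride
        p = self.pad
        kh = kw = self.kernel
        c = self.in_ch
        dout_mat = dout.reshape(n * ho * wo, self.out_ch)
        self.W.grad += (cols.T @ dout_mat).reshape(self.W.value.shape)
        self.b.grad += dout_mat.sum(axis=0)
        # input gradient = full correlation of the (dilated) output gradient
        # with the flipped kernel — one im2col matmul instead of a scatter
        hd, wd = (ho - 1) * sh + 1, (wo - 1) * sw + 1
        dd = np.zeros((n, hd + 2 * (kh - 1), wd + 2 * (kw - 1), self.out_ch),
                      dtype=dout.dtype)
        dd[:, kh - 1:kh - 1 + hd:sh, kw - 1:kw - 1 + wd:sw, :] = dout
        v = sliding_window_view(dd, (kh, kw), axis=(1, 2))
        vcols = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3)
                                     ).reshape(-1, kh * kw * self.out_ch)
        w_flip = np.ascontiguousarray(
            self.W.value[::-1, ::-1].transpose(0, 1, 3, 2)
        ).reshape(-1, c)
        dxp_full = (vcols @ w_flip).reshape(n, hd + kh - 1, wd + kw - 1, c)
        hp, wp = xp_shape[1], xp_shape[2]
        dxp = np.zeros(xp_shape, dtype=dout.dtype)
        dxp[:, :min(hp, dxp_full.shape[1]), :min(wp, dxp_full.shape[2]), :] = \
            dxp_full[:, :hp, :wp, :]
        h, w = x_shape[1], x_shape[2]
        return dxp[:, p:p + h, p:p + w, :]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None, name: str = "dense",
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.W = Param(w.astype(dtype), f"{name}.W")
        self.b = Param(np.zeros(n_out, dtype=dtype), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape

    def forward(self, x):
        return x.reshape(x.shape[0], *self.shape)

    def backward(self, dout):
        return dout.reshape(dout.shape[0], -1)


class Upsample(Layer):
    """Nearest-neighbour upsampling by integer factors, cropped to a target size."""

    def __init__(self, factor: tuple[int, int], target: tuple[int, int]):
        self.factor = factor
        self.target = target

    def forward(self, x):
        fh, fw = self.factor
        th, tw = self.target
        y = x.repeat(fh, axis=1).repeat(fw, axis=2)
        self._in_hw = x.shape[1:3]
        return y[:, :th, :tw, :]

    def backward(self, dout):
        fh, fw = self.factor
        h, w = self._in_hw
        n, _, _, ch = dout.shape
        full = np.zeros((n, h * fh, w * fw, ch), dtype=dout.dtype)
        full[:, :dout.shape[1], :dout.shape[2], :] = dout
        return full.reshape(n, h, fh, w, fw, ch).sum(axis=(2, 4))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam with decoupled weight decay (decay applied to weights only)."""

    def __init__(self, params: list[Param], lr: float = 3e-4,
                 weight_decay: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            update = (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            if self.weight_decay and p.value.ndim > 1:
                update = update + self.weight_decay * p.value
            p.value -= self.lr * update
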