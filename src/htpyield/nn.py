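"""A compact numpy CNN engine: layers, backprop and Adam.

Just enough machinery for small image-regression networks on CPU: 2-d
convolution (stride 1, optional zero padding), batch normalization, ReLU,
average/max pooling, dropout, dense layers and a scalar regression head,
trained by mini-batch Adam on a mean-squared-error loss. Convolution runs as
k*k shifted batched matmuls (cheap at the kernel sizes used here); everything
is float32.

Layers expose forward(x, train) / backward(dout) and keep their parameters
and gradients in dicts so the optimizer can walk them generically.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """3x3-ish convolution, stride 1. Input (N, C, H, W) -> (N, O, H', W')."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, pad: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.kernel = kernel
        self.pad = pad
        self.params = {
            "W": (rng.standard_normal((out_ch, in_ch, kernel, kernel)) * np.sqrt(2.0 / fan_in)).astype(np.float32),
            "b": np.zeros(out_ch, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train):
        k, p = self.kernel, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        N, C, H, Wd = x.shape
        OH, OW = H - k + 1, Wd - k + 1
        # im2col: one GEMM per batch instead of per-tap products
        sw = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        cols = np.ascontiguousarray(sw.transpose(0, 2, 3, 1, 4, 5)).reshape(N * OH * OW, C * k * k)
        self._cols, self._in_shape, self._out_hw = cols, x.shape, (OH, OW)
        W = self.params["W"]
        out = cols @ W.reshape(W.shape[0], -1).T + self.params["b"]
        return np.ascontiguousarray(out.reshape(N, OH, OW, -1).transpose(0, 3, 1, 2))

    def backward(self, dout):
        k, p = self.kernel, self.pad
        N, C, H, Wd = self._in_shape
        OH, OW = self._out_hw
        W = self.params["W"]
        O = W.shape[0]
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(N * OH * OW, O)
        self.grads["W"] = (dmat.T @ self._cols).reshape(W.shape)
        self.grads["b"] = dmat.sum(axis=0)
        dcols = (dmat @ W.reshape(O, -1)).reshape(N, OH, OW, C, k, k)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + OH, j : j + OW] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            dx = dx[:, :, p:-p, p:-p]
        return dx


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(ch, dtype=np.float32), "beta": np.zeros(ch, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._xhat, self._std = xhat, std
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dout):
        xhat, std = self._xhat, self._std
        N = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        # standard batchnorm backward over the (N, H, W) axes
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / std[None, :, None, None]
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class AvgPool2d(Layer):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train):
        s = self.size
        N, C, H, W = x.shape
        if H % s or W % s:
            raise ValueError(f"feature map {H}x{W} not divisible by pool size {s}")
        self._shape = x.shape
        return x.reshape(N, C, H // s, s, W // s, s).mean(axis=(3, 5))

    def backward(self, dout):
        s = self.size
        return np.repeat(np.repeat(dout, s, axis=2), s, axis=3) / (s * s)


class MaxPool2d(Layer):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train):
        s = self.size
        N, C, H, W = x.shape
        if H % s or W % s:
            raise ValueError(f"feature map {H}x{W} not divisible by pool size {s}")
        xr = x.reshape(N, C, H // s, s, W // s, s)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, dout):
        s = self.size
        dr = self._mask * dout[:, :, :, None, :, None]
        # split ties evenly so gradient mass is conserved
        ties = self._mask.sum(axis=(3, 5), keepdims=True)
        dr = dr / ties
        return dr.reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        N, C, H, W = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (H * W)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(np.float32),
            "b": np.zeros(d_out, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        for layer in self.layers:
            for key in layer.params:
                yield layer, key

    def n_params(self) -> int:
        return sum(v.size for layer in self.layers for v in layer.params.values())

    def state(self) -> list[dict]:
        out = []
        for layer in self.layers:
            d = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, BatchNorm2d):
                d["_running_mean"] = layer.running_mean.copy()
                d["_running_var"] = layer.running_var.copy()
            out.append(d)
        return out

    def load_state(self, state: list[dict]) -> None:
        for layer, d in zip(self.layers, state):
            for k, v in d.items():
                if k == "_running_mean":
                    layer.running_mean = v.copy()
                elif k == "_running_var":
                    layer.running_var = v.copy()
                else:
                    layer.params[k] = v.copy()


class Adam:
    """Adam with the standard bias correction; state per parameter tensor."""

    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, key in self.model.parameters():
            g = layer.grads[key]
            sk = (id(layer), key)
            m = self._m.get(sk)
            v = self._v.get(sk)
            if m is None:
                m = np.zeros_like(g)
                v = np.zeros_like(g)
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self._m[sk], self._v[sk] = m, v
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. pred."""
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size
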