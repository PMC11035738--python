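"""Minimal NumPy neural-network layers for small convolutional classifiers.

Implements exactly what the lesioning experiments need: im2col 2-D
convolution, batch normalization, ReLU, residual blocks, global average
pooling, a fully connected head, and SGD with momentum.  Forward and
backward passes are plain float32 NumPy; convolutions are lowered to GEMMs
so the whole stack runs acceptably on one CPU at 112x112 inputs.

Layers follow a tiny protocol: ``forward(x, train)`` caches whatever the
backward pass needs, ``backward(dy)`` returns the gradient w.r.t. the
layer input and fills ``grads`` for every entry of ``params``.  A layer
must be run forward before backward, and caches are overwritten on each
forward call (no graph retention).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "GlobalAvgPool",
    "Linear",
    "ResidualBlock",
    "Sequential",
    "SGDMomentum",
]


class Layer:
    """Base layer: parameter/gradient dicts plus the forward/backward protocol."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    # state_dict helpers: flat name -> array, suitable for np.savez
    def state_arrays(self) -> dict[str, np.ndarray]:
        return dict(self.params)

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k][...] = state[k]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Lower a padded NCHW tensor to a (N*Ho*Wo, C*k*k) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, hp, wp = x.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N, C, Ho, Wo, k, k) -> (N, Ho, Wo, C, k, k) -> (N*Ho*Wo, C*k*k)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n * ho * wo, c * k * k), (n, c, hp, wp, ho, wo)


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k // 2) if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.params = {"W": w.astype(np.float32),
                       "b": np.zeros(cout, dtype=np.float32)}
        self.zero_grads()
        self._cache = None

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        cols, geom = _im2col(x, self.k, self.stride, self.pad)
        n, c, hp, wp, ho, wo = geom
        wr = self.params["W"].reshape(self.cout, -1)
        out = cols @ wr.T + self.params["b"]
        self._cache = (cols, geom)
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, (n, c, hp, wp, ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        dyr = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.grads["W"] = (dyr.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] = dyr.sum(axis=0)
        dcols = (dyr @ self.params["W"].reshape(self.cout, -1))
        dcols = dcols.reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
        # fold patches back: one strided add per kernel offset
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:hp - p, p:wp - p]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.c, self.momentum, self.eps = c, momentum, eps
        self.params = {"gamma": np.ones(c, dtype=np.float32),
                       "beta": np.zeros(c, dtype=np.float32)}
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.zero_grads()
        self._cache = None

    def forward(self, x, train=False):
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
            self._cache = ("train", xhat, invstd)
            return (g * xhat + b).astype(np.float32)
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        self._cache = ("eval", None, invstd)
        xhat = (x - self.running_mean[None, :, None, None]) * invstd[None, :, None, None]
        return (g * xhat + b).astype(np.float32)

    def backward(self, dy):
        mode, xhat, invstd = self._cache
        g = self.params["gamma"]
        if mode == "eval":
            return dy * (g * invstd)[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g[None, :, None, None]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dy.sum(axis=(0, 2, 3))
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        return dx.astype(np.float32)

    def state_arrays(self):
        d = dict(self.params)
        d["running_mean"] = self.running_mean
        d["running_var"] = self.running_var
        return d

    def load_state_arrays(self, state):
        super().load_state_arrays(state)
        self.running_mean[...] = state["running_mean"]
        self.running_var[...] = state["running_var"]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class GlobalAvgPool(Layer):
    """NCHW -> NC spatial mean."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w),
                               self._shape).astype(np.float32)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(1.0 / cin)
        self.params = {"W": rng.uniform(-bound, bound, size=(cout, cin)).astype(np.float32),
                       "b": np.zeros(cout, dtype=np.float32)}
        self.zero_grads()

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = dy.T @ self._x
        self.grads["b"] = dy.sum(axis=0)
        return (dy @ self.params["W"]).astype(np.float32)


class ResidualBlock(Layer):
    """Two 3x3 conv+BN stages with an identity or projected skip connection."""

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(cin, cout, 3, stride, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.project = stride != 1 or cin != cout
        if self.project:
            self.conv_sc = Conv2d(cin, cout, 1, stride, pad=0, rng=rng)
            self.bn_sc = BatchNorm2d(cout)
        self.relu_out = ReLU()

    def _children(self):
        names = ["conv1", "bn1", "relu1", "conv2", "bn2", "relu_out"]
        if self.project:
            names += ["conv_sc", "bn_sc"]
        return [(n, getattr(self, n)) for n in names]

    def forward(self, x, train=False):
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.bn2.forward(h, train)
        if self.project:
            sc = self.bn_sc.forward(self.conv_sc.forward(x, train), train)
        else:
            sc = x
        return self.relu_out.forward(h + sc, train)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dmain = self.bn2.backward(d)
        dmain = self.conv2.backward(dmain)
        dmain = self.relu1.backward(dmain)
        dmain = self.bn1.backward(dmain)
        dmain = self.conv1.backward(dmain)
        if self.project:
            dsc = self.conv_sc.backward(self.bn_sc.backward(d))
        else:
            dsc = d
        return dmain + dsc

    def zero_grads(self):
        for _, child in self._children():
            child.zero_grads()

    def state_arrays(self):
        out = {}
        for name, child in self._children():
            for k, v in child.state_arrays().items():
                out[f"{name}.{k}"] = v
        return out

    def load_state_arrays(self, state):
        for name, child in self._children():
            sub = {k.split(".", 1)[1]: v for k, v in state.items()
                   if k.startswith(name + ".")}
            child.load_state_arrays(sub)

    def param_items(self):
        for name, child in self._children():
            if isinstance(child, ResidualBlock):
                yield from child.param_items()
            else:
                for k in child.params:
                    yield f"{name}.{k}", child.params, child.grads, k


class Sequential:
    """Ordered layer stack with optional activation capture for Grad-CAM.

    ``capture_index`` names a layer whose *output* is recorded during
    ``forward``; ``backward_to_capture`` then backpropagates an output-side
    gradient through the tail layers only and returns d(out)/d(captured).
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.captured: np.ndarray | None = None

    def forward(self, x, train=False, capture_index: int | None = None):
        self.captured = None
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train)
            if capture_index is not None and i == capture_index:
                self.captured = x
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def backward_to_capture(self, dy, capture_index: int):
        for layer in reversed(self.layers[capture_index + 1:]):
            dy = layer.backward(dy)
        return dy

    def zero_grads(self):
        for layer in self.layers:
            layer.zero_grads()

    def param_items(self):
        """Yield (flat_name, params_dict, grads_dict, key) over all leaves."""
        for i, layer in enumerate(self.layers):
            if isinstance(layer, ResidualBlock):
                for name, p, g, k in layer.param_items():
                    yield f"layer{i}.{name}", p, g, k
            else:
                for k in layer.params:
                    yield f"layer{i}.{k}", layer.params, layer.grads, k

    def state_arrays(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state_arrays().items():
                out[f"layer{i}.{k}"] = v
        return out

    def load_state_arrays(self, state):
        for i, layer in enumerate(self.layers):
            prefix = f"layer{i}."
            sub = {k[len(prefix):]: v for k, v in state.items()
                   if k.startswith(prefix)}
            layer.load_state_arrays(sub)


class SGDMomentum:
    """Classic momentum SGD: v <- mu v - lr g; p <- p + v."""

    def __init__(self, model: Sequential, lr: float = 0.01, momentum: float = 0.9):
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self._velocity: dict[str, np.ndarray] = {}

    def step(self):
        for name, params, grads, k in self.model.param_items():
            v = self._velocity.get(name)
            if v is None:
                v = np.zeros_like(params[k])
            v = self.momentum * v - self.lr * grads[k]
            self._velocity[name] = v
            params[k] += v
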