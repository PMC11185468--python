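"""Minimal NumPy feed-forward layer library.

Implements exactly what layer-wise CAM introspection needs from a deep-learning
substrate: sequential models whose every leaf layer exposes its forward output,
the gradient of a class logit with respect to that output, and a parameter
census.  Training support (cross-entropy + Adam) exists so that synthetic
classifiers can be fitted end-to-end inside the test-bed.

Conventions: activations are ``float64`` arrays shaped ``(B, C, H, W)`` for
spatial layers and ``(B, F)`` after flattening.  Layers cache their last
forward input, so ``backward`` must follow the matching ``forward``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Dropout",
    "Identity",
    "StopGradient",
    "ChannelMask",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy",
    "NonDifferentiableError",
]


class NonDifferentiableError(RuntimeError):
    """Raised when a gradient is requested through a layer with no gradient path."""


class Layer:
    """Base class: a leaf module with parameters, a forward and a backward."""

    kind: str = "generic"
    #: pass-through layers (identity, inference-mode dropout) are excluded from
    #: target-layer enumeration by default
    enumerable: bool = True
    differentiable: bool = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    @property
    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    b, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((b, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(b, c * k * k, ho * wo), (ho, wo)


def _col2im(gcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    b, c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    g6 = gcols.reshape(b, c, k, k, ho, wo)
    gxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    for i in range(k):
        for j in range(k):
            gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += g6[:, :, i, j]
    if pad:
        return gxp[:, :, pad : pad + h, pad : pad + w]
    return gxp


class Conv2d(Layer):
    kind = "conv"

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.stride, self.padding = stride, padding
        fan_in = in_channels * kernel_size * kernel_size
        rng = rng or np.random.default_rng(0)
        # He initialization, suitable for ReLU networks
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, kernel_size, kernel_size))
        self.params["weight"] = w
        if bias:
            self.params["bias"] = np.zeros(out_channels)
        self.zero_grad()

    def forward(self, x, train=False):
        self._x_shape = x.shape
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.padding)
        self._cols = cols
        wmat = self.params["weight"].reshape(self.cout, -1)
        out = np.einsum("of,bfp->bop", wmat, cols)
        if "bias" in self.params:
            out = out + self.params["bias"][None, :, None]
        return out.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, gy):
        b = gy.shape[0]
        gflat = gy.reshape(b, self.cout, -1)
        self.grads["weight"] += np.einsum("bop,bfp->of", gflat, self._cols).reshape(self.params["weight"].shape)
        if "bias" in self.params:
            self.grads["bias"] += gflat.sum(axis=(0, 2))
        wmat = self.params["weight"].reshape(self.cout, -1)
        gcols = np.einsum("of,bop->bfp", wmat, gflat)
        return _col2im(gcols, self._x_shape, self.k, self.stride, self.padding)


class BatchNorm2d(Layer):
    kind = "norm"

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["weight"] = np.ones(channels)
        self.params["bias"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.zero_grad()

    def forward(self, x, train=False):
        self._train = train
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            n = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            # unbiased variance for the running estimate, as is conventional
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var * n / max(n - 1, 1)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._inv_std[None, :, None, None]
        return self.params["weight"][None, :, None, None] * self._xhat + self.params["bias"][None, :, None, None]

    def backward(self, gy):
        self.grads["weight"] += (gy * self._xhat).sum(axis=(0, 2, 3))
        self.grads["bias"] += gy.sum(axis=(0, 2, 3))
        g = self.params["weight"][None, :, None, None]
        if not self._train:
            return gy * g * self._inv_std[None, :, None, None]
        n = gy.shape[0] * gy.shape[2] * gy.shape[3]
        gxhat = gy * g
        s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (gxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (gxhat - s1 / n - self._xhat * s2 / n) * self._inv_std[None, :, None, None]


class ReLU(Layer):
    kind = "act"

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy):
        return np.where(self._mask, gy, 0.0)


class MaxPool2d(Layer):
    """2x2 stride-2 max pooling; spatial extents must be even."""

    kind = "pool"

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d requires even spatial extents, got {(h, w)}")
        self._x_shape = x.shape
        r = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        self._arg = r.argmax(axis=-1)
        return r.max(axis=-1)

    def backward(self, gy):
        b, c, h, w = self._x_shape
        gr = np.zeros((b, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(gr, self._arg[..., None], gy[..., None], axis=-1)
        return gr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)


class GlobalAvgPool(Layer):
    kind = "pool"

    def forward(self, x, train=False):
        self._x_shape = x.shape
        return x.mean(axis=(2, 3), keepdims=True)

    def backward(self, gy):
        b, c, h, w = self._x_shape
        return np.broadcast_to(gy / (h * w), self._x_shape).copy()


class Flatten(Layer):
    kind = "reshape"

    def forward(self, x, train=False):
        self._x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._x_shape)


class Linear(Layer):
    kind = "linear"

    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["weight"] = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        if bias:
            self.params["bias"] = np.zeros(out_features)
        self.zero_grad()

    def forward(self, x, train=False):
        self._x = x
        out = x @ self.params["weight"].T
        if "bias" in self.params:
            out = out + self.params["bias"]
        return out

    def backward(self, gy):
        self.grads["weight"] += gy.T @ self._x
        if "bias" in self.params:
            self.grads["bias"] += gy.sum(axis=0)
        return gy @ self.params["weight"]


class Dropout(Layer):
    """Inference-mode pass-through; a stochastic mask is only drawn in training."""

    kind = "dropout"
    enumerable = False

    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.p = p
        self._rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Identity(Layer):
    kind = "identity"
    enumerable = False

    def forward(self, x, train=False):
        return x

    def backward(self, gy):
        return gy


class StopGradient(Layer):
    """Identity forward with no gradient path (for gradient-free-layer handling)."""

    kind = "stopgrad"
    differentiable = False

    def forward(self, x, train=False):
        return x

    def backward(self, gy):
        raise NonDifferentiableError("no gradient path through StopGradient")


class ChannelMask(Layer):
    """Multiplies each channel by a fixed spatial mask (no parameters)."""

    kind = "mask"

    def __init__(self, masks: np.ndarray) -> None:
        super().__init__()
        self.masks = np.asarray(masks, dtype=float)  # (C, H, W)

    def forward(self, x, train=False):
        return x * self.masks[None]

    def backward(self, gy):
        return gy * self.masks[None]


# ---------------------------------------------------------------------------
# sequential container


class Sequential:
    """An ordered chain of named leaf layers with activation/gradient capture.

    Parameters
    ----------
    named_layers
        ``(name, layer)`` pairs in forward execution order.  The same layer
        object may appear more than once (weight sharing); introspection then
        keeps the final invocation.
    input_shape
        Shape of a single input sample, e.g. ``(1, 64, 64)``; used to probe
        the model with a dummy input during layer enumeration.
    """

    def __init__(self, named_layers: list[tuple[str, Layer]], input_shape: tuple[int, ...]):
        self.layers = list(named_layers)
        self.input_shape = tuple(input_shape)
        self.training = False

    # -- mode ----------------------------------------------------------------
    def train(self):
        self.training = True
        return self

    def eval(self):
        self.training = False
        return self

    # -- execution -----------------------------------------------------------
    def _as_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape == self.input_shape:
            x = x[None]
        return x

    def forward(self, x: np.ndarray, train: bool | None = None) -> np.ndarray:
        train = self.training if train is None else train
        h = self._as_batch(x)
        for _, layer in self.layers:
            h = layer.forward(h, train=train)
        return h

    def forward_collect(self, x: np.ndarray):
        """Forward pass recording the output of every layer (inference mode)."""
        h = self._as_batch(x)
        acts = []
        for _, layer in self.layers:
            h = layer.forward(h, train=False)
            acts.append(h)
        return h, acts

    def backward_collect(self, grad_out: np.ndarray):
        """Gradients of a scalar-through-``grad_out`` w.r.t. each layer output.

        Must directly follow :meth:`forward_collect`.  Returns a list aligned
        with the layer list; entries upstream of a non-differentiable layer
        are ``None``.
        """
        n = len(self.layers)
        grads: list[np.ndarray | None] = [None] * n
        grads[n - 1] = grad_out
        g = grad_out
        for i in range(n - 1, -1, -1):
            try:
                g = self.layers[i][1].backward(g)
            except NonDifferentiableError:
                break
            if i > 0:
                grads[i - 1] = g
        return grads

    def forward_from(self, index: int, activation: np.ndarray) -> np.ndarray:
        """Resume the forward pass after layer ``index`` from a given activation."""
        h = np.asarray(activation, dtype=float)
        for _, layer in self.layers[index + 1 :]:
            h = layer.forward(h, train=False)
        return h

    # -- parameters ----------------------------------------------------------
    def parameters(self):
        seen: set[int] = set()
        for name, layer in self.layers:
            if id(layer) in seen:
                continue
            seen.add(id(layer))
            for pname, arr in layer.params.items():
                yield layer, f"{name}.{pname}", arr

    def zero_grad(self):
        for _, layer in self.layers:
            layer.zero_grad()

    @property
    def total_params(self) -> int:
        return int(sum(arr.size for _, _, arr in self.parameters()))

    def param_checksum(self) -> float:
        return float(sum(np.abs(arr).sum() for _, _, arr in self.parameters()))

    def state_copy(self) -> list[np.ndarray]:
        return [arr.copy() for _, _, arr in self.parameters()]


# ---------------------------------------------------------------------------
# loss and optimizer


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return loss, g / n


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-2, betas=(0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr, self.betas, self.eps = lr, betas, eps
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.betas
        for layer, full_name, arr in self.model.parameters():
            pname = full_name.rsplit(".", 1)[1]
            g = layer.grads[pname]
            key = (id(layer), pname)
            m = self._m.setdefault(key, np.zeros_like(arr))
            v = self._v.setdefault(key, np.zeros_like(arr))
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
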