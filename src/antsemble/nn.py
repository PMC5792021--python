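"""A compact numpy CNN engine: layers, backprop, and SGD with momentum.

Implements exactly the operations the architecture descriptors declare:
im2col convolution, overlapping max pooling, AlexNet-style local response
normalization across channels, fully connected layers, ReLU, inverted
dropout, and a fused softmax/cross-entropy loss.  Everything runs on float32
CPU arrays; all randomness (weight initialisation, dropout masks) flows from
generators supplied by the caller, so training is reproducible bit-for-bit on
a fixed backend.

Tensors are laid out ``(N, C, H, W)``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .netspec import ArchitectureDescriptor, output_size

__all__ = [
    "Layer",
    "Conv2d",
    "MaxPool2d",
    "LocalResponseNorm",
    "Flatten",
    "Linear",
    "ReLU",
    "Dropout",
    "Network",
    "softmax",
    "softmax_cross_entropy",
    "compile_network",
    "SGDMomentum",
]


class Layer:
    """Base layer: ``forward(x, train)`` then ``backward(grad)``.

    ``params``/``grads`` are parallel lists of float32 arrays (empty for
    parameter-free layers); ``decayable`` flags which params receive weight
    decay (weight matrices yes, biases no).
    """

    params: list[np.ndarray]
    grads: list[np.ndarray]
    decayable: list[bool]

    def __init__(self) -> None:
        self.params, self.grads, self.decayable = [], [], []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, padding: int):
    """Unfold ``(N,C,H,W)`` into ``(N*Ho*Wo, C*k*k)`` patch rows."""
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = output_size(h, k, padding, stride)
    wo = output_size(w, k, padding, stride)
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    col = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(col), ho, wo


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with ``C_out`` receptive fields."""

    def __init__(self, in_channels: int, out_channels: int, k: int,
                 stride: int, padding: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout = in_channels, out_channels
        self.k, self.stride, self.padding = k, stride, padding
        fan_in = in_channels * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(fan_in, out_channels)).astype(np.float32)
        b = np.zeros(out_channels, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.decayable = [True, False]

    def forward(self, x, train=False):
        self._xshape = x.shape
        col, ho, wo = _im2col(x, self.k, self.stride, self.padding)
        self._col, self._ho, self._wo = col, ho, wo
        w, b = self.params
        out = col @ w + b
        return out.reshape(x.shape[0], ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, _, h, w_in = self._xshape
        k, s, p = self.k, self.stride, self.padding
        w, _ = self.params
        ho, wo = self._ho, self._wo
        g = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        self.grads[0][...] = self._col.T @ g
        self.grads[1][...] = g.sum(axis=0)
        dcol = (g @ w.T).reshape(n, ho, wo, self.cin, k, k)
        dxp = np.zeros((n, self.cin, h + 2 * p, w_in + 2 * p), dtype=np.float32)
        # fold patch gradients back; k*k vectorised scatter-adds
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + s * ho:s, dj:dj + s * wo:s] += \
                    dcol[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class MaxPool2d(Layer):
    """Max pooling with a k x k window; windows may overlap (e.g. 3x3/2)."""

    def __init__(self, k: int, stride: int):
        super().__init__()
        self.k, self.stride = k, stride

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s = self.k, self.stride
        ho = output_size(h, k, 0, s)
        wo = output_size(w, k, 0, s)
        windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        windows = windows[:, :, ::s, ::s].reshape(n, c, ho, wo, k * k)
        self._argmax = windows.argmax(axis=-1)
        self._inshape = x.shape
        return windows.max(axis=-1)

    def backward(self, grad):
        n, c, h, w = self._inshape
        k, s = self.k, self.stride
        _, _, ho, wo = grad.shape
        rows = (np.arange(ho) * s)[None, None, :, None] + self._argmax // k
        cols = (np.arange(wo) * s)[None, None, None, :] + self._argmax % k
        dx = np.zeros(self._inshape, dtype=np.float32)
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dx, (np.broadcast_to(ni, rows.shape),
                       np.broadcast_to(ci, rows.shape), rows, cols), grad)
        return dx


class LocalResponseNorm(Layer):
    """Across-channel local response normalization.

    ``b_i = a_i / (k + (alpha/n) * sum_{j near i} a_j^2)^beta`` with the
    AlexNet window ``n=5`` and ``alpha=1e-4, beta=0.75, k=1``.
    """

    def __init__(self, n: int = 5, alpha: float = 1e-4, beta: float = 0.75,
                 k: float = 1.0):
        super().__init__()
        self.n, self.alpha, self.beta, self.k = n, alpha, beta, k

    def _window_sum(self, x):
        half = self.n // 2
        out = np.zeros_like(x)
        c = x.shape[1]
        for off in range(-half, half + 1):
            lo, hi = max(0, -off), min(c, c - off)
            out[:, lo:hi] += x[:, lo + off:hi + off]
        return out

    def forward(self, x, train=False):
        sq = x * x
        denom = self.k + (self.alpha / self.n) * self._window_sum(sq)
        self._x, self._denom = x, denom
        self._scale = denom ** (-self.beta)
        return x * self._scale

    def backward(self, grad):
        x, denom = self._x, self._denom
        t = grad * x * denom ** (-self.beta - 1.0)
        cross = self._window_sum(t)
        return grad * self._scale - (2.0 * self.alpha * self.beta / self.n) * x * cross


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    """Fully connected layer: weighted sum of all cells of all channels."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features),
                       size=(in_features, out_features)).astype(np.float32)
        b = np.zeros(out_features, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.decayable = [True, False]

    def forward(self, x, train=False):
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, grad):
        w, _ = self.params
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ w.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout: scaling happens at train time, inference is identity."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        rng = self.rng if self.rng is not None else np.random.default_rng()
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(np.float32).tiny
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


class Network:
    """An ordered stack of layers compiled from an architecture descriptor."""

    def __init__(self, layers: list[Layer], linear_indices: list[int]):
        self.layers = layers
        self.linear_indices = linear_indices  # positions of Linear layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def forward_collect(self, x: np.ndarray) -> list[np.ndarray]:
        """Inference forward pass returning the output of every layer."""
        outs = []
        for layer in self.layers:
            x = layer.forward(x, train=False)
            outs.append(x)
        return outs

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    # -- parameter plumbing ------------------------------------------------
    def parameters(self):
        for layer in self.layers:
            for p, g, d in zip(layer.params, layer.grads, layer.decayable):
                yield p, g, d

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(state):
            raise ValueError("state does not match network parameter count")
        for p, s in zip(flat, state):
            if p.shape != s.shape:
                raise ValueError("state shape mismatch")
            p[...] = s

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng


def compile_network(arch: ArchitectureDescriptor,
                    rng: np.random.Generator) -> Network:
    """Instantiate a :class:`Network` from a descriptor.

    Softmax and loss layers are declarative terminators: the compiled network
    outputs logits, and :func:`softmax_cross_entropy` / :func:`softmax` apply
    the terminal operations.  A flatten step is inserted before the first
    fully connected layer.
    """
    layers: list[Layer] = []
    linear_indices: list[int] = []
    h = arch.input_size
    c = arch.input_channels
    flattened = False
    for spec in arch.layers:
        if spec.kind in ("input", "softmax", "loss"):
            continue
        if spec.kind == "convolution":
            layers.append(Conv2d(c, spec.out_channels, spec.k, spec.stride,
                                 spec.padding or 0, rng))
            h = output_size(h, spec.k, spec.padding or 0, spec.stride)
            c = spec.out_channels
        elif spec.kind == "pooling":
            layers.append(MaxPool2d(spec.k, spec.stride))
            h = output_size(h, spec.k, 0, spec.stride)
        elif spec.kind == "normalization":
            layers.append(LocalResponseNorm())
        elif spec.kind == "fully_connected":
            if not flattened:
                layers.append(Flatten())
                flattened = True
                in_features = c * h * h
            else:
                in_features = c
            linear_indices.append(len(layers))
            layers.append(Linear(in_features, spec.out_channels, rng))
            c, h = spec.out_channels, 1
        elif spec.kind == "relu":
            layers.append(ReLU())
        elif spec.kind == "dropout":
            layers.append(Dropout(spec.rate))
        else:  # pragma: no cover - guarded by LayerSpec validation
            raise ValueError(f"cannot compile layer kind {spec.kind!r}")
    return Network(layers, linear_indices)


class SGDMomentum:
    """Stochastic gradient descent with classical momentum and weight decay."""

    def __init__(self, net: Network, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.net = net
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p) for p, _, _ in net.parameters()]

    def step(self) -> None:
        for v, (p, g, decay) in zip(self.velocity, self.net.parameters()):
            grad = g
            if decay and self.weight_decay:
                grad = g + self.weight_decay * p
            v *= self.momentum
            v -= self.lr * grad
            p += v
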