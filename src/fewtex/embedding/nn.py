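"""Minimal CNN engine (numpy): layers, Adam, and the backbone contract.

Implements exactly what the embedding stage needs — 3x3 convolutions,
ReLU, 2x2 max pooling, global average pooling, dense layers, softmax
cross-entropy and Adam — with deterministic seeded initialization.
Arrays are NCHW.  The engine is CPU-only and sized for desk-scale
experiments; a heavier pretrained backbone can be plugged in through the
same ``Backbone`` contract.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "Conv2d", "ReLU", "MaxPool2", "GlobalAvgPool", "Dense",
           "Backbone", "TinyConvBackbone", "Model", "Adam",
           "softmax_cross_entropy", "swap_classifier"]


class Layer:
    """Forward/backward unit with optional parameters."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[dict]:
        return []


class Conv2d(Layer):
    """3x3 (or kxk) convolution, stride 1, 'same' zero padding, via im2col."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        self.w = rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(out_ch)
        self.k = k
        self.in_ch, self.out_ch = in_ch, out_ch
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        view = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # n,c,h,w,k,k
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        out = cols @ self.w.T + self.b
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.dw = g.T @ cols
        self.db = g.sum(axis=0)
        dcols = (g @ self.w).reshape(n, h, w, c, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki:ki + h, kj:kj + w] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]

    def params(self) -> list[dict]:
        return [{"layer": self, "name": "w"}, {"layer": self, "name": "b"},]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        xr = x[:, :, :ho * 2, :wo * 2].reshape(n, c, ho, 2, wo, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        ho, wo = h // 2, w // 2
        onehot = np.eye(4)[self._idx]  # n,c,ho,wo,4
        g = (grad[..., None] * onehot).reshape(n, c, ho, wo, 2, 2)
        out = np.zeros((n, c, h, w))
        out[:, :, :ho * 2, :wo * 2] = g.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho * 2, wo * 2)
        return out


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None, relu_gain: bool = True):
        rng = rng or np.random.default_rng(0)
        gain = 2.0 if relu_gain else 1.0
        self.w = rng.standard_normal((in_dim, out_dim)) * np.sqrt(gain / in_dim)
        self.b = np.zeros(out_dim)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self) -> list[dict]:
        return [{"layer": self, "name": "w"}, {"layer": self, "name": "b"},]


class Backbone:
    """Contract: a sequence of layers mapping NCHW images to (N, feature_dim)."""

    layers: list[Layer]
    feature_dim: int
    in_channels: int = 1


class TinyConvBackbone(Backbone):
    """Four 3x3 conv blocks (8, 16, 32, 64 channels), each ReLU + 2x2 pool,
    followed by global average pooling to a 64-d pooled feature.

    Sized so that desk-scale training on small grayscale images completes
    in seconds on one CPU while still producing class-discriminative
    embeddings on well-separated textures.
    """

    def __init__(self, seed: int = 0, channels: tuple[int, ...] = (8, 16, 32, 64)):
        rng = np.random.default_rng(seed)
        self.layers = []
        prev = self.in_channels
        for ch in channels:
            self.layers += [Conv2d(prev, ch, rng=rng), ReLU(), MaxPool2()]
            prev = ch
        self.layers.append(GlobalAvgPool())
        self.feature_dim = prev


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-300)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Model:
    """Backbone + fully connected head + softmax classifier."""

    def __init__(self, backbone: Backbone, head_layers: list[Layer], classifier: Dense, head_widths: tuple[int, ...]):
        self.backbone = backbone
        self.head_layers = head_layers
        self.classifier = classifier
        self.head_widths = tuple(head_widths)

    @property
    def embedding_dim(self) -> int:
        return self.head_widths[-1]

    def _feature_layers(self) -> list[Layer]:
        return list(self.backbone.layers) + list(self.head_layers)

    def forward_features(self, x: np.ndarray) -> np.ndarray:
        for layer in self._feature_layers():
            x = layer.forward(x)
        return x

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        return self.classifier.forward(self.forward_features(x))

    def backward(self, grad_logits: np.ndarray) -> None:
        grad = self.classifier.backward(grad_logits)
        for layer in reversed(self._feature_layers()):
            grad = layer.backward(grad)

    def parameters(self) -> list[dict]:
        out = []
        for layer in self._feature_layers() + [self.classifier]:
            out += layer.params()
        return out

    def feature_weights_snapshot(self) -> list[np.ndarray]:
        return [getattr(p["layer"], p["name"]).copy()
                for layer in self._feature_layers() for p in layer.params()]


def swap_classifier(model: Model, n_classes: int, seed: int = 0) -> Model:
    """Replace the classifier layer, retaining every other learned weight."""
    rng = np.random.default_rng(seed)
    new_clf = Dense(model.embedding_dim, n_classes, rng=rng, relu_gain=False)
    return Model(model.backbone, model.head_layers, new_clf, model.head_widths)


class Adam:
    def __init__(self, params: list[dict], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(p["layer"], p["name"])) for p in params]
        self.v = [np.zeros_like(getattr(p["layer"], p["name"])) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            layer, name = p["layer"], p["name"]
            g = getattr(layer, "d" + name)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            val = getattr(layer, name)
            setattr(layer, name, val - self.lr * mhat / (np.sqrt(vhat) + self.eps))
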