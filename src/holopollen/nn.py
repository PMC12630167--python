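"""Minimal deterministic neural-network layers with manual backprop.

Implements exactly what the two-branch pollen classifier needs — 3x3
convolutions (im2col), ReLU, 2x2 max pooling, dense layers, softmax
cross-entropy and Adam — in pure numpy, so that training is reproducible
bit-for-bit from a single seed on one CPU.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 (shape preserving)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / (cin * 9))
        self.w = Param(rng.normal(0, scale, (cout, cin, 3, 3)).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self._cols = None
        self._shape = None

    def params(self):
        return [self.w, self.b]

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = sliding_window_view(xp, (3, 3), axis=(2, 3))
        # (N, C, H, W, 3, 3) -> (N*H*W, C*9)
        n, c, h, w = x.shape
        return np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * 9
        )

    def forward(self, x):
        n, c, h, w = x.shape
        cols = self._im2col(x)
        self._cols, self._shape = cols, x.shape
        cout = self.w.value.shape[0]
        out = cols @ self.w.value.reshape(cout, c * 9).T + self.b.value
        return out.reshape(n, h, w, cout).transpose(0, 3, 1, 2)

    def backward(self, g):
        n, cout, h, w = g.shape
        cin = self._shape[1]
        gf = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        self.w.grad += (gf.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad += gf.sum(axis=0)
        # input gradient = correlation of g with the flipped kernels
        gcols = self._im2col(g)
        v = np.flip(self.w.value, axis=(2, 3)).transpose(0, 2, 3, 1).reshape(
            cout * 9, cin
        )
        dx = (gcols @ v).reshape(n, h, w, cin).transpose(0, 3, 1, 2)
        self._cols = None
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; spatial dims must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(out, self._idx[..., None], g[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / nin)
        self.w = Param(rng.normal(0, scale, (nout, nin)).astype(dtype))
        self.b = Param(np.zeros(nout, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, g):
        self.w.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class TwoBranchNet:
    """Convolutional hologram branch + small dense fluorescence branch.

    The hologram branch is a stack of VGG-style blocks (3x3 convolutions
    with ReLU, 2x2 pooling after each block) over the two stacked
    hologram planes, flattened into ``image_features`` units.  The
    fluorescence branch maps the 13 channels plus a presence flag through
    ``fluor_hidden_units`` units.  The two feature vectors are
    concatenated into a linear softmax head.  Absent fluorescence is
    encoded as a zero vector with presence flag 0.
    """

    def __init__(
        self,
        image_side: int,
        conv_blocks: Sequence[Tuple[int, int]],
        fluor_hidden_units: int,
        n_classes: int,
        rng_seed: int,
        image_features: int = 32,
        fluor_input: int = 14,
        dtype=np.float32,
    ):
        if not conv_blocks:
            raise ConfigurationError("at least one conv block is required")
        if fluor_hidden_units < 1:
            raise ConfigurationError("fluor_hidden_units must be >= 1")
        side = image_side
        for _ in conv_blocks:
            if side % 2 != 0:
                raise ConfigurationError(
                    f"image_side {image_side} is not divisible by 2 at every "
                    f"of the {len(conv_blocks)} pooling stages"
                )
            side //= 2
        if side < 1:
            raise ConfigurationError(
                f"image_side {image_side} too small for {len(conv_blocks)} blocks"
            )
        rng = np.random.default_rng(rng_seed)
        self.dtype = dtype
        self.image_side = image_side
        self.conv_blocks = [tuple(b) for b in conv_blocks]
        self.fluor_hidden_units = fluor_hidden_units
        self.n_classes = n_classes
        self.image_features = image_features

        layers: List[Layer] = []
        cin = 2
        for channels, n_layers in conv_blocks:
            for _ in range(n_layers):
                layers += [Conv3x3(cin, channels, rng, dtype), ReLU()]
                cin = channels
            layers.append(MaxPool2())
        layers.append(Flatten())
        flat = cin * side * side
        layers += [Dense(flat, image_features, rng, dtype), ReLU()]
        self.image_branch = Sequential(layers)
        self.fluor_branch = Sequential(
            [Dense(fluor_input, fluor_hidden_units, rng, dtype), ReLU()]
        )
        self.head = Dense(
            image_features + fluor_hidden_units, n_classes, rng, dtype
        )

    def params(self) -> List[Param]:
        return (
            self.image_branch.params()
            + self.fluor_branch.params()
            + [*self.head.params()]
        )

    def forward(self, images: np.ndarray, fluor: np.ndarray) -> np.ndarray:
        """Logits for a batch; images (N,2,S,S), fluor (N,14)."""
        images = np.asarray(images, dtype=self.dtype)
        fluor = np.asarray(fluor, dtype=self.dtype)
        a = self.image_branch.forward(images)
        b = self.fluor_branch.forward(fluor)
        self._split = a.shape[1]
        return self.head.forward(np.concatenate([a, b], axis=1))

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.head.backward(dlogits)
        self.image_branch.backward(dz[:, : self._split])
        self.fluor_branch.backward(dz[:, self._split:])

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-300)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
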