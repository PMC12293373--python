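"""Minimal 3D-convolutional network engine in numpy.

Layers implement ``forward(x, train)`` / ``backward(grad_out)`` with explicit
caches, so a :class:`Sequential` stack supports exact reverse-mode gradients
without any ambient state. Convolution is computed by extracting strided
patches (``sliding_window_view``) and contracting with ``einsum``; its
backward pass scatters patch gradients back with one strided add per kernel
offset. All parameter initialisation draws from a ``numpy.random.Generator``
passed in by the caller — there is no global RNG use anywhere.

Gradient correctness of every layer is enforced by finite-difference tests;
the engine is deliberately small (no autodiff graph, no broadcasting
gymnastics) because the encoders built on it are small.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: holds params/grads dicts keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution over (batch, channels, depth, height, width).

    Symmetric zero padding, isotropic stride. Weight layout is
    (out_channels, in_channels, kd, kh, kw).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 stride: int = 1, padding: int = 1, *, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel ** 3
        # He initialisation, appropriate for the ReLU nonlinearity that follows
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels, kernel, kernel, kernel))
        self.params = {"W": w, "b": np.zeros(out_channels)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p, s, k = self.padding, self.stride, self.kernel
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        # patches: (B, C, D', H', W', k, k, k) after stride subsampling
        patches = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        patches = patches[:, :, ::s, ::s, ::s]
        out = np.einsum("bcdhwxyz,ocxyz->bodhw", patches,
                        self.params["W"], optimize=True)
        out += self.params["b"][None, :, None, None, None]
        if train:
            self._cache = (x.shape, xp.shape, patches)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward() before forward(train=True)")
        x_shape, xp_shape, patches = self._cache
        k, s, p = self.kernel, self.stride, self.padding
        self.grads["W"][...] = np.einsum(
            "bodhw,bcdhwxyz->ocxyz", grad_out, patches, optimize=True)
        self.grads["b"][...] = grad_out.sum(axis=(0, 2, 3, 4))
        # gradient w.r.t. each patch, then scatter-add back into the padded input
        dpatches = np.einsum("bodhw,ocxyz->bcdhwxyz", grad_out,
                             self.params["W"], optimize=True)
        dxp = np.zeros(xp_shape)
        nd, nh, nw = grad_out.shape[2:]
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    dxp[:, :, a:a + nd * s:s, b:b + nh * s:s, c:c + nw * s:s] \
                        += dpatches[:, :, :, :, :, a, b, c]
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        self._cache = None
        return np.ascontiguousarray(dxp.reshape(x_shape))


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        grad = grad_out * self._mask
        self._mask = None
        return grad


class GlobalAvgPool3d(Layer):
    """Adaptive global average pooling: (B, C, D, H, W) -> (B, C).

    Output length depends only on the channel count, so the stack tolerates
    any input spatial size.
    """

    def __init__(self) -> None:
        super().__init__()
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        b, c, d, h, w = self._in_shape
        self._in_shape = None
        g = grad_out[:, :, None, None, None] / float(d * h * w)
        return np.broadcast_to(g, (b, c, d, h, w)).copy()


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(1.0 / in_features)
        self.params = {
            "W": rng.uniform(-bound, bound, size=(out_features, in_features)),
            "b": np.zeros(out_features),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = grad_out.T @ self._x
        self.grads["b"][...] = grad_out.sum(axis=0)
        grad = grad_out @ self.params["W"]
        self._x = None
        return grad


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def named_params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, param, grad) triples over all layers, in stable order."""
        out = []
        for i, layer in enumerate(self.layers):
            for key in sorted(layer.params):
                out.append((f"{i}.{type(layer).__name__}.{key}",
                            layer.params[key], layer.grads[key]))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, p, _ in self.named_params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {name: p for name, p, _ in self.named_params()}
        if set(own) != set(state):
            raise KeyError("parameter names do not match this architecture")
        for name, p in own.items():
            if p.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p[...] = state[name]


class Adam:
    """Adam optimizer over any object exposing ``named_params()``."""

    def __init__(self, net, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(p) for name, p, _ in net.named_params()}
        self.v = {name: np.zeros_like(p) for name, p, _ in net.named_params()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p, g in self.net.named_params():
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1 ** self.t)
            vhat = self.v[name] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for _, _, g in self.net.named_params():
            g[...] = 0.0


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch and its gradient w.r.t. the logits.

    ``logits``: (B, n_classes); ``labels``: (B,) integer class ids.
    """
    shifted = logits - logits.max(axis=1, keepdims=True)
    logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    n = logits.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    grad = np.exp(logp)
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n
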