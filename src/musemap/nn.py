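"""Minimal CPU neural-network toolkit (numpy forward/backward).

Supports exactly what the translation and classification networks need:
2-D convolution (zero padding, stride), instance normalisation, residual
blocks, nearest-neighbour upsampling, global average pooling, dense layers,
LSGAN/L1/cross-entropy losses, and SGD/Adam optimisers.

Layers are *functional*: ``forward`` returns ``(out, cache)`` and
``backward(cache, grad)`` returns the input gradient while accumulating
parameter gradients into ``layer.grads``.  Because each forward call owns
its cache, one network can appear several times in a single training graph
(as the generators do in a cycle-consistency step).

Arrays are NCHW ``float32``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d", "Dense", "ReLU", "LeakyReLU", "Tanh", "InstanceNorm",
    "Upsample2x", "GlobalAvgPool", "Flatten", "Sequential", "ResBlock",
    "SGD", "Adam", "softmax", "cross_entropy_with_logits",
]


class Layer:
    """Base class: parameter-free layers inherit as-is."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, cache, grad: np.ndarray):  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def layers(self) -> list["Layer"]:
        return [self]


class Conv2d(Layer):
    """k x k convolution, zero padding, integer stride.

    Implemented as a sum over kernel offsets of channel-mixing einsums,
    which keeps memory flat (no im2col copy) and is fast for small kernels.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.params["w"] = (scale * rng.standard_normal((c_out, c_in, k, k))
                            ).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self.zero_grads()

    def forward(self, x: np.ndarray):
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        n, _, hp, wp = xp.shape
        ho, wo = (hp - k) // s + 1, (wp - k) // s + 1
        w = self.params["w"]
        out = np.broadcast_to(
            self.params["b"][None, :, None, None], (n, w.shape[0], ho, wo)
        ).copy()
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
                out += np.einsum("oc,nchw->nohw", w[:, :, i, j], xs, optimize=True)
        return out, xp

    def backward(self, cache, grad: np.ndarray):
        xp = cache
        k, s, p = self.k, self.stride, self.pad
        ho, wo = grad.shape[2], grad.shape[3]
        w = self.params["w"]
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
                self.grads["w"][:, :, i, j] += np.einsum(
                    "nohw,nchw->oc", grad, xs, optimize=True)
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += np.einsum(
                    "oc,nohw->nchw", w[:, :, i, j], grad, optimize=True)
        self.grads["b"] += grad.sum(axis=(0, 2, 3))
        return dxp[:, :, p:xp.shape[2] - p, p:xp.shape[3] - p] if p else dxp


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.params["w"] = (scale * rng.standard_normal((n_out, n_in))).astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)
        self.zero_grads()

    def forward(self, x: np.ndarray):
        return x @ self.params["w"].T + self.params["b"], x

    def backward(self, cache, grad: np.ndarray):
        x = cache
        self.grads["w"] += grad.T @ x
        self.grads["b"] += grad.sum(axis=0)
        return grad @ self.params["w"]


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, cache, grad):
        return grad * cache


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, cache, grad):
        return np.where(cache, grad, self.slope * grad)


class Tanh(Layer):
    def forward(self, x):
        out = np.tanh(x)
        return out, out

    def backward(self, cache, grad):
        return grad * (1.0 - cache ** 2)


class InstanceNorm(Layer):
    """Per-sample, per-channel normalisation over spatial dims, with affine."""

    def __init__(self, c: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params["g"] = np.ones(c, dtype=np.float32)
        self.params["b"] = np.zeros(c, dtype=np.float32)
        self.zero_grads()

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        out = self.params["g"][None, :, None, None] * xhat + self.params["b"][None, :, None, None]
        return out, (xhat, inv)

    def backward(self, cache, grad):
        xhat, inv = cache
        m = xhat.shape[2] * xhat.shape[3]
        self.grads["g"] += (grad * xhat).sum(axis=(0, 2, 3))
        self.grads["b"] += grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.params["g"][None, :, None, None]
        # standard normalisation backward, per (n, c)
        dx = (dxhat - dxhat.mean(axis=(2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(2, 3), keepdims=True)) * inv
        return dx


class Upsample2x(Layer):
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3), x.shape

    def backward(self, cache, grad):
        n, c, h, w = cache
        return grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x):
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, cache, grad):
        n, c, h, w = cache
        return np.broadcast_to(grad[:, :, None, None] / (h * w), (n, c, h, w)).copy()


class Flatten(Layer):
    def forward(self, x):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, cache, grad):
        return grad.reshape(cache)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self._layers = list(layers)

    def forward(self, x):
        caches = []
        for layer in self._layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, cache, grad):
        for layer, c in zip(reversed(self._layers), reversed(cache)):
            grad = layer.backward(c, grad)
        return grad

    def layers(self):
        out: list[Layer] = []
        for layer in self._layers:
            out.extend(layer.layers())
        return out


class ResidualAdd(Layer):
    """out = clip(x + body(x), -1, 1): a bounded correction-field head.

    Starting near the identity map keeps identity/cycle objectives
    well-behaved from the first step.  The clip uses a leaky backward pass
    (slope ``leak`` outside the range) so saturated pixels keep receiving
    gradient and can be pulled back into range instead of staying pinned.
    """

    def __init__(self, body: Layer, leak: float = 0.1):
        super().__init__()
        self.body = body
        self.leak = leak

    def forward(self, x):
        y, cache = self.body.forward(x)
        s = x + y
        out = np.clip(s, -1.0, 1.0)
        inside = (s > -1.0) & (s < 1.0)
        return out, (cache, inside)

    def backward(self, cache, grad):
        body_cache, inside = cache
        g = np.where(inside, grad, self.leak * grad)
        return g + self.body.backward(body_cache, g)

    def layers(self):
        return self.body.layers()


class ResBlock(Layer):
    """x + conv(relu(conv(x))), channel-preserving."""

    def __init__(self, c: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.body = Sequential(Conv2d(c, c, 3, rng=rng), ReLU(),
                               Conv2d(c, c, 3, rng=rng))

    def forward(self, x):
        y, cache = self.body.forward(x)
        return x + y, cache

    def backward(self, cache, grad):
        return grad + self.body.backward(cache, grad)

    def layers(self):
        return self.body.layers()


# --------------------------------------------------------------------------
# network-level utilities


def zero_grads(net: Layer) -> None:
    for layer in net.layers():
        layer.zero_grads()


def get_weights(net: Layer) -> list[dict[str, np.ndarray]]:
    return [{k: v.copy() for k, v in layer.params.items()} for layer in net.layers()]


def set_weights(net: Layer, weights: list[dict[str, np.ndarray]]) -> None:
    for layer, w in zip(net.layers(), weights, strict=True):
        for k in layer.params:
            layer.params[k][...] = w[k]


def save_weights(path, nets: dict[str, Layer]) -> None:
    """Save one or more networks into a single .npz archive."""
    payload = {}
    for name, net in nets.items():
        for i, layer in enumerate(net.layers()):
            for k, v in layer.params.items():
                payload[f"{name}/{i}/{k}"] = v
    np.savez(path, **payload)


def load_weights(path, nets: dict[str, Layer]) -> None:
    with np.load(path) as archive:
        for name, net in nets.items():
            for i, layer in enumerate(net.layers()):
                for k in layer.params:
                    layer.params[k][...] = archive[f"{name}/{i}/{k}"]


# --------------------------------------------------------------------------
# losses


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_logits(z: np.ndarray, y: np.ndarray
                              ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. logits."""
    p = softmax(z)
    n = z.shape[0]
    loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
    dz = p.copy()
    dz[np.arange(n), y] -= 1.0
    return loss, (dz / n).astype(np.float32)


def mse_to(scores: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Least-squares GAN objective term: mean((scores - target)^2)."""
    d = scores - target
    return float((d ** 2).mean()), (2.0 * d / d.size).astype(np.float32)


def l1_to(x: np.ndarray, ref: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute difference and its (sub)gradient w.r.t. x."""
    d = x - ref
    return float(np.abs(d).mean()), (np.sign(d) / d.size).astype(np.float32)


# --------------------------------------------------------------------------
# optimisers


class SGD:
    def __init__(self, nets: list[Layer], lr: float, momentum: float = 0.9):
        self.items = [layer for net in nets for layer in net.layers() if layer.params]
        self.lr, self.momentum = lr, momentum
        self.vel = {(id(l), k): np.zeros_like(v)
                    for l in self.items for k, v in l.params.items()}

    def step(self) -> None:
        for layer in self.items:
            for k, p in layer.params.items():
                v = self.vel[(id(layer), k)]
                v *= self.momentum
                v -= self.lr * layer.grads[k]
                p += v


class Adam:
    def __init__(self, nets: list[Layer], lr: float,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.items = [layer for net in nets for layer in net.layers() if layer.params]
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = {(id(l), k): np.zeros_like(v)
                  for l in self.items for k, v in l.params.items()}
        self.v = {(id(l), k): np.zeros_like(v)
                  for l in self.items for k, v in l.params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for layer in self.items:
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[(id(layer), k)]
                v = self.v[(id(layer), k)]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
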