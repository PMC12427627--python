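"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module is the numerical substrate for every trainable component in the
package: the additive behavioral network, the CNN-GNN volume encoder, the
fusion autoencoder, and the hypernetwork classifier.  It implements exactly
the operations those models need -- broadcast-aware elementwise arithmetic,
(batched) matrix multiplication, ReLU/sigmoid, reductions, reshapes, a
structured 3x3x3 volumetric convolution, two numerically stable
classification losses -- plus the Adam optimizer.

Design constraints:
  * float64 throughout, so gradient checks against central differences are
    meaningful at ~1e-7 tolerance;
  * no global random state -- every weight initializer takes an explicit
    ``numpy.random.Generator``;
  * graphs are built eagerly per forward pass and freed after ``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "add",
    "sub",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "abs_",
    "square",
    "sum_",
    "mean_",
    "reshape",
    "getitem",
    "dropout",
    "bce_with_logits",
    "softmax_cross_entropy",
    "softmax",
    "Conv3d",
    "Linear",
    "Adam",
    "glorot",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self._parents
        )

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Accumulate gradients of self (summed to a scalar) into the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return mul(self, -1.0)


def parameter(data):
    """A trainable leaf tensor."""
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def constant(data):
    """A non-trainable leaf tensor."""
    return Tensor(data)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray):
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# Elementwise -----------------------------------------------------------


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, (a, b), bwd)


def sub(a, b):
    return add(a, mul(b, -1.0))


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def bwd(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, (a, b), bwd)


def matmul(a, b):
    """Batched matrix product; both operands must be >= 2-D."""
    a, b = _as_tensor(a), _as_tensor(b)
    if a.data.ndim < 2 or b.data.ndim < 2:
        raise ValueError("matmul operands must be at least 2-D")
    out_data = a.data @ b.data

    def bwd(g):
        _accumulate(a, _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        _accumulate(b, _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    return Tensor(out_data, (a, b), bwd)


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0)

    def bwd(g):
        _accumulate(a, g * mask)

    return Tensor(out_data, (a,), bwd)


def sigmoid(a):
    a = _as_tensor(a)
    out_data = _sigmoid_np(a.data)

    def bwd(g):
        _accumulate(a, g * out_data * (1.0 - out_data))

    return Tensor(out_data, (a,), bwd)


def _sigmoid_np(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def abs_(a):
    a = _as_tensor(a)
    out_data = np.abs(a.data)

    def bwd(g):
        _accumulate(a, g * np.sign(a.data))

    return Tensor(out_data, (a,), bwd)


def square(a):
    a = _as_tensor(a)

    def bwd(g):
        _accumulate(a, 2.0 * g * a.data)

    return Tensor(a.data**2, (a,), bwd)


# Reductions and shape --------------------------------------------------


def sum_(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accumulate(a, np.broadcast_to(g, a.data.shape).copy())

    return Tensor(out_data, (a,), bwd)


def mean_(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape):
    a = _as_tensor(a)
    orig = a.data.shape

    def bwd(g):
        _accumulate(a, g.reshape(orig))

    return Tensor(a.data.reshape(shape), (a,), bwd)


def getitem(a, key):
    """Basic (slice) indexing with gradient scatter."""
    a = _as_tensor(a)
    out_data = a.data[key]

    def bwd(g):
        full = np.zeros_like(a.data)
        full[key] = g
        _accumulate(a, full)

    return Tensor(out_data, (a,), bwd)


def dropout(a, rate: float, rng: np.random.Generator, training: bool):
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return _as_tensor(a)
    mask = (rng.random(_as_tensor(a).data.shape) >= rate) / (1.0 - rate)
    return mul(a, constant(mask))


# Losses ----------------------------------------------------------------


def bce_with_logits(logits: Tensor, y: np.ndarray):
    """Mean binary cross-entropy over logits, stable for large |logit|.

    ``y`` is a plain 0/1 array broadcastable to ``logits``.
    """
    logits = _as_tensor(logits)
    y = np.asarray(y, dtype=np.float64).reshape(logits.data.shape)
    x = logits.data
    # log(1 + exp(-|x|)) + max(x, 0) - x*y, elementwise
    loss_el = np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0) - x * y
    n = x.size

    def bwd(g):
        _accumulate(logits, g * (_sigmoid_np(x) - y) / n)

    return Tensor(loss_el.mean(), (logits,), bwd)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, y: np.ndarray):
    """Mean cross-entropy of integer labels ``y`` against (n, K) logits."""
    logits = _as_tensor(logits)
    y = np.asarray(y, dtype=np.intp)
    p = softmax(logits.data)
    n = logits.data.shape[0]
    eps = 1e-300
    loss = -np.log(p[np.arange(n), y] + eps).mean()

    def bwd(g):
        d = p.copy()
        d[np.arange(n), y] -= 1.0
        _accumulate(logits, g * d / n)

    return Tensor(loss, (logits,), bwd)


# Layers ----------------------------------------------------------------


def glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-limit, limit, size=shape))


class Linear:
    """Dense layer ``x @ W + b`` for 2-D inputs."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 weight_scale: float | None = None):
        if weight_scale is None:
            self.W = glorot(rng, (in_dim, out_dim), in_dim, out_dim)
        else:
            self.W = parameter(rng.normal(0.0, weight_scale, (in_dim, out_dim)))
        self.b = parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.W), self.b)

    def parameters(self):
        return [self.W, self.b]


class Conv3d:
    """3x3x3 convolution (stride 1, zero padding) over a fixed spatial grid.

    Inputs and outputs are laid out as ``(batch, n_voxels, channels)`` with
    voxels enumerated in C order of the spatial shape; padding preserves the
    grid so that atlas masks keep aligning with feature maps.  The kernel is
    applied as a sum over the 27 spatial offsets of (shifted slice of the
    padded volume) @ (per-offset weight block) -- slicing gives strided
    views, so no per-voxel patch matrix is ever materialized, and the input
    gradient is the mirrored accumulation into the padded gradient volume.
    """

    KSIZE = 27  # 3*3*3

    def __init__(self, in_channels: int, out_channels: int,
                 spatial_shape: tuple, rng: np.random.Generator):
        self.cin = int(in_channels)
        self.cout = int(out_channels)
        self.shape = tuple(int(s) for s in spatial_shape)
        if len(self.shape) != 3:
            raise ValueError("spatial_shape must be 3-D")
        self.V = int(np.prod(self.shape))
        self.offsets = [(dz, dy, dx)
                        for dz in range(3) for dy in range(3) for dx in range(3)]
        fan_in = self.KSIZE * self.cin
        # W rows are ordered offset-major: rows [k*cin:(k+1)*cin] belong to tap k
        self.W = glorot(rng, (fan_in, self.cout), fan_in, self.cout)
        self.b = parameter(np.zeros(self.cout))

    def _views(self, xpad: np.ndarray):
        d, h, w = self.shape
        for k, (dz, dy, dx) in enumerate(self.offsets):
            yield k, xpad[:, dz:dz + d, dy:dy + h, dx:dx + w, :]

    def __call__(self, x: Tensor) -> Tensor:
        x = _as_tensor(x)
        if x.data.ndim != 3 or x.data.shape[1] != self.V or x.data.shape[2] != self.cin:
            raise ValueError(
                f"expected input of shape (B, {self.V}, {self.cin}), got {x.data.shape}"
            )
        B = x.data.shape[0]
        d, h, w = self.shape
        W, b = self.W, self.b
        xpad = np.zeros((B, d + 2, h + 2, w + 2, self.cin))
        xpad[:, 1:-1, 1:-1, 1:-1, :] = x.data.reshape(B, d, h, w, self.cin)
        acc = np.zeros((B, d, h, w, self.cout)) + b.data
        for k, view in self._views(xpad):
            acc += view @ W.data[k * self.cin:(k + 1) * self.cin]
        out_data = acc.reshape(B, self.V, self.cout)

        def bwd(g):
            g4 = g.reshape(B, d, h, w, self.cout)
            if b.requires_grad:
                _accumulate(b, g.sum(axis=(0, 1)))
            dxpad = np.zeros_like(xpad) if x.requires_grad else None
            if W.requires_grad:
                dW = np.empty_like(W.data)
            for k, view in self._views(xpad):
                rows = slice(k * self.cin, (k + 1) * self.cin)
                if W.requires_grad:
                    dW[rows] = np.tensordot(view, g4, axes=([0, 1, 2, 3],
                                                            [0, 1, 2, 3]))
                if dxpad is not None:
                    dz, dy, dx = self.offsets[k]
                    dxpad[:, dz:dz + d, dy:dy + h, dx:dx + w, :] += (
                        g4 @ W.data[rows].T
                    )
            if W.requires_grad:
                _accumulate(W, dW)
            if dxpad is not None:
                _accumulate(
                    x, dxpad[:, 1:-1, 1:-1, 1:-1, :].reshape(B, self.V, self.cin)
                )

        return Tensor(out_data, (x, W, b), bwd)

    def parameters(self):
        return [self.W, self.b]


# Optimizer -------------------------------------------------------------


class Adam:
    """Adam with the standard bias correction (Kingma & Ba defaults)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
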