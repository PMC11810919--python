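"""Minimal reverse-mode automatic differentiation and neural-network layers on NumPy.

The segmentation models in this package are small, fully convolutional
encoder–decoder networks trained at desk scale on a CPU.  This module provides
exactly the primitives they need: a :class:`Tensor` that records a backward
closure per operation, 2D convolution (stride 1, "same" padding, odd kernels),
2x2/stride-2 transposed convolution, max/average pooling, batch normalization,
dense layers, the usual activations, and an Adam optimizer.

Conventions
-----------
* Feature maps are ``(N, C, H, W)`` arrays; descriptor vectors are ``(N, C)``.
* Convolution gradients w.r.t. the input are computed as a same-padded
  correlation of the upstream gradient with the spatially flipped kernel
  (exact for stride 1), so no scatter-add is needed.
* All floating-point work defaults to ``float32``; tests that perform numeric
  gradient checks switch :data:`DEFAULT_DTYPE` to ``float64``.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32


class Tensor:
    """An array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self._parents
        )

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate ``grad`` (default: ones) through the recorded graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be a few hundred nodes deep
            node, processed = stack.pop()
            if id(node) in seen or not node.requires_grad:
                continue
            if processed:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen:
                        stack.append((p, False))
        for t in topo:
            t.grad = None
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DEFAULT_DTYPE), requires_grad=True)


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0)

    def bwd(g):
        x.accumulate(g * (x.data > 0))

    return Tensor(y, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    from scipy.special import expit

    y = expit(x.data)

    def bwd(g):
        x.accumulate(g * y * (1.0 - y))

    return Tensor(y, (x,), bwd)


def add(a: Tensor, b: Tensor) -> Tensor:
    y = a.data + b.data

    def bwd(g):
        a.accumulate(g)
        b.accumulate(g)

    return Tensor(y, (a, b), bwd)


def concat(tensors, axis=1) -> Tensor:
    y = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t.accumulate(g[tuple(idx)])

    return Tensor(y, tuple(tensors), bwd)


def average(tensors) -> Tensor:
    """Elementwise mean of same-shaped tensors."""
    k = len(tensors)
    y = sum(t.data for t in tensors) / k

    def bwd(g):
        gk = g / k
        for t in tensors:
            t.accumulate(gk)

    return Tensor(y, tuple(tensors), bwd)


def sum_tensors(tensors) -> Tensor:
    """Elementwise sum of same-shaped tensors."""
    y = sum(t.data for t in tensors)

    def bwd(g):
        for t in tensors:
            t.accumulate(g)

    return Tensor(y, tuple(tensors), bwd)


def channel_gate(x: Tensor, s: Tensor) -> Tensor:
    """Multiply feature map ``x`` (N,C,H,W) by per-channel weights ``s`` (N,C)."""
    y = x.data * s.data[:, :, None, None]

    def bwd(g):
        x.accumulate(g * s.data[:, :, None, None])
        s.accumulate((g * x.data).sum(axis=(2, 3)))

    return Tensor(y, (x, s), bwd)


# ---------------------------------------------------------------------------
# convolutions and pooling
# ---------------------------------------------------------------------------


def _cols(x: np.ndarray, k: int) -> np.ndarray:
    """im2col for same-padded odd-kernel correlation: (N,C,H,W) -> (N, H*W, C*k*k)."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, h * w, c * k * k
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 2D correlation with bias.  ``w``: (Cout, Cin, k, k)."""
    n, cin, h, wid = x.data.shape
    cout, _, k, _ = w.data.shape
    cols = _cols(x.data, k)
    out = cols @ w.data.reshape(cout, -1).T
    out += b.data
    y = out.transpose(0, 2, 1).reshape(n, cout, h, wid)

    def bwd(g):
        gm = g.transpose(0, 2, 3, 1).reshape(n * h * wid, cout)
        b.accumulate(gm.sum(axis=0))
        dwm = gm.T @ cols.reshape(n * h * wid, -1)
        w.accumulate(dwm.reshape(w.data.shape))
        if x.requires_grad:
            wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gcols = _cols(g, k)
            dx = gcols @ wflip.reshape(cin, -1).T
            x.accumulate(dx.transpose(0, 2, 1).reshape(n, cin, h, wid))

    return Tensor(y, (x, w, b), bwd)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2, stride-2 transposed convolution (doubles H and W).  ``w``: (Cin, Cout, 2, 2)."""
    n, cin, h, wd = x.data.shape
    cout = w.data.shape[1]
    t = np.tensordot(x.data, w.data, axes=([1], [0]))  # (N,H,W,Cout,2,2)
    y = np.ascontiguousarray(t.transpose(0, 3, 1, 4, 2, 5)).reshape(
        n, cout, 2 * h, 2 * wd
    )
    y += b.data[:, None, None]

    def bwd(g):
        gr = g.reshape(n, cout, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)
        b.accumulate(g.sum(axis=(0, 2, 3)))
        w.accumulate(np.tensordot(x.data, gr, axes=([0, 2, 3], [0, 1, 2])))
        if x.requires_grad:
            dx = np.tensordot(gr, w.data, axes=([3, 4, 5], [1, 2, 3]))
            x.accumulate(dx.transpose(0, 3, 1, 2))

    return Tensor(y, (x, w, b), bwd)


def maxpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    mask = xr == y[:, :, :, None, :, None]

    def bwd(g):
        x.accumulate((mask * g[:, :, :, None, :, None]).reshape(n, c, h, w))

    return Tensor(y, (x,), bwd)


def avgpool(x: Tensor, f: int) -> Tensor:
    """Non-overlapping average pooling with window = stride = ``f``."""
    n, c, h, w = x.data.shape
    y = x.data.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

    def bwd(g):
        gx = np.broadcast_to(
            g[:, :, :, None, :, None] / (f * f), (n, c, h // f, f, w // f, f)
        )
        x.accumulate(gx.reshape(n, c, h, w))

    return Tensor(y, (x,), bwd)


def global_avgpool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    n, c, h, w = x.data.shape
    y = x.data.mean(axis=(2, 3))

    def bwd(g):
        x.accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    return Tensor(y, (x,), bwd)


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Fully connected layer on (N, Cin) vectors.  ``w``: (Cout, Cin)."""
    y = x.data @ w.data.T + b.data

    def bwd(g):
        b.accumulate(g.sum(axis=0))
        w.accumulate(g.T @ x.data)
        if x.requires_grad:
            x.accumulate(g @ w.data)

    return Tensor(y, (x, w, b), bwd)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Module:
    """Base class with recursive parameter / buffer / submodule discovery."""

    def parameters(self) -> list[Parameter]:
        out = []
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Parameter):
                    out.append(v)
        return out

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        out = []
        for m in self.modules():
            out.extend(getattr(m, "_buffers", []))
        return out

    def modules(self):
        found = [self]
        stack = [self]
        while stack:
            m = stack.pop()
            for v in vars(m).values():
                items = v if isinstance(v, (list, tuple)) else [v]
                for it in items:
                    if isinstance(it, Module) and it not in found:
                        found.append(it)
                        stack.append(it)
        return found

    def state(self) -> list[np.ndarray]:
        """Copies of all parameters and buffers, for checkpointing."""
        return [p.data.copy() for p in self.parameters()] + [
            b.copy() for b in self.buffers()
        ]

    def load_state(self, state) -> None:
        params = self.parameters()
        bufs = self.buffers()
        assert len(state) == len(params) + len(bufs)
        for p, s in zip(params, state[: len(params)]):
            p.data[...] = s
        for b, s in zip(bufs, state[len(params):]):
            b[...] = s


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DEFAULT_DTYPE)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.w = Parameter(he_init(rng, (cout, cin, k, k), cin * k * k))
        self.b = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Parameter(he_init(rng, (cin, cout, 2, 2), cin * 4))
        self.b = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.w, self.b)


class Dense(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Parameter(he_init(rng, (cout, cin), cin))
        self.b = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return dense(x, self.w, self.b)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics.

    ``momentum`` is the decay of the running averages; 0.9 adapts quickly
    enough that evaluation-mode statistics are usable after a few hundred
    desk-scale training steps.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c, dtype=DEFAULT_DTYPE)
        self.running_var = np.ones(c, dtype=DEFAULT_DTYPE)
        self._buffers = [self.running_mean, self.running_var]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        gamma, beta = self.gamma, self.beta
        if training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean *= m
            self.running_mean += (1 - m) * mu.astype(self.running_mean.dtype)
            self.running_var *= m
            self.running_var += (1 - m) * var.astype(self.running_var.dtype)
        else:
            mu = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[:, None, None]) * inv_std[:, None, None]
        y = gamma.data[:, None, None] * xhat + beta.data[:, None, None]

        def bwd(g):
            beta.accumulate(g.sum(axis=(0, 2, 3)))
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if not x.requires_grad:
                return
            dxhat = g * gamma.data[:, None, None]
            if training:
                n = g.shape[0] * g.shape[2] * g.shape[3]
                s1 = dxhat.sum(axis=(0, 2, 3))
                s2 = (dxhat * xhat).sum(axis=(0, 2, 3))
                dx = (
                    inv_std[:, None, None]
                    / n
                    * (n * dxhat - s1[:, None, None] - xhat * s2[:, None, None])
                )
            else:
                dx = dxhat * inv_std[:, None, None]
            x.accumulate(dx)

        return Tensor(y, (x, gamma, beta), bwd)


class Adam:
    """Adam optimizer; zeroes gradients after each step."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.grad = None


# ---------------------------------------------------------------------------
# loss nodes (scalar outputs with analytic gradients)
# ---------------------------------------------------------------------------


def dice_loss_node(probs: Tensor, masks: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Soft Dice loss, computed per image then averaged over the batch.

    ``probs``: (N,1,H,W) probabilities; ``masks``: (N,H,W) binary.
    """
    p = probs.data[:, 0]
    g = masks.astype(p.dtype)
    inter = (p * g).sum(axis=(1, 2))
    num = 2.0 * inter + eps
    den = p.sum(axis=(1, 2)) + g.sum(axis=(1, 2)) + eps
    losses = 1.0 - num / den
    nb = len(losses)

    def bwd(gout):
        dp = -(2.0 * g * den[:, None, None] - num[:, None, None]) / (
            den[:, None, None] ** 2
        )
        probs.accumulate(gout * dp[:, None] / nb)

    return Tensor(losses.mean(), (probs,), bwd)


def bce_loss_node(probs: Tensor, masks: np.ndarray, clamp: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy over all pixels and the batch."""
    p = np.clip(probs.data[:, 0], clamp, 1.0 - clamp)
    g = masks.astype(p.dtype)
    val = -(g * np.log(p) + (1.0 - g) * np.log(1.0 - p)).mean()
    npix = p.size

    def bwd(gout):
        dp = (-g / p + (1.0 - g) / (1.0 - p)) / npix
        probs.accumulate(gout * dp[:, None])

    return Tensor(val, (probs,), bwd)
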