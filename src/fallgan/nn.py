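"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the primitives the frame-prediction networks need:
elementwise arithmetic, tanh / leaky-ReLU, reductions, 2-D convolution
(im2col-based), nearest-neighbour 2x upsampling, global average pooling,
and an Adam optimizer.  Everything runs in float64 for reproducibility.

The engine is deliberately small: tensors form a DAG of closures and
``Tensor.backward`` walks it in reverse topological order (the classic
micrograd pattern, vectorized over arrays).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def _accumulate(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: Array | None = None, retain_graph: bool = False) -> None:
        """Reverse-mode sweep; frees the graph afterwards unless retained.

        Freeing (dropping each node's parents and backward closure)
        breaks the closure reference cycles so large intermediate arrays
        are reclaimed immediately by reference counting rather than
        waiting for the cyclic garbage collector.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        if not retain_graph:
            for node in topo:
                node._backward = None
                node._parents = ()
                if not node.requires_grad and node is not self:
                    node.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    def free_graph(self) -> "Tensor":
        """Drop the autograd graph below this tensor (forward-only use).

        Breaks closure reference cycles so intermediates are reclaimed
        promptly; returns self for chaining.
        """
        stack: list[Tensor] = [self]
        seen: set[int] = set()
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.extend(node._parents)
            node._backward = None
            node._parents = ()
        return self

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out = _make(self.data + other.data, (self, other))

        def _bw():
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = _make(-self.data, (self,))
        out._backward = lambda: self._accumulate(-out.grad)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out = _make(self.data * other.data, (self, other))

        def _bw():
            self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out = _make(self.data / other.data, (self, other))

        def _bw():
            self._accumulate(_unbroadcast(out.grad / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-out.grad * self.data / other.data**2, other.data.shape)
            )

        out._backward = _bw
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        out = _make(self.data**exponent, (self,))

        def _bw():
            self._accumulate(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = _bw
        return out

    def abs(self) -> "Tensor":
        out = _make(np.abs(self.data), (self,))
        out._backward = lambda: self._accumulate(out.grad * np.sign(self.data))
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = _make(y, (self,))
        out._backward = lambda: self._accumulate(out.grad * (1.0 - y**2))
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = np.where(self.data > 0, 1.0, slope)
        out = _make(self.data * mask, (self,))
        out._backward = lambda: self._accumulate(out.grad * mask)
        return out

    # -- reductions / shape ops ----------------------------------------------
    def sum(self) -> "Tensor":
        out = _make(self.data.sum(), (self,))
        out._backward = lambda: self._accumulate(
            np.full_like(self.data, float(out.grad))
        )
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out = _make(self.data.mean(), (self,))
        out._backward = lambda: self._accumulate(
            np.full_like(self.data, float(out.grad) / n)
        )
        return out

    def mean_axes(self, axes: tuple[int, ...], keepdims: bool = True) -> "Tensor":
        out_data = self.data.mean(axis=axes, keepdims=keepdims)
        n = self.data.size // out_data.size
        out = _make(out_data, (self,))

        def _bw():
            g = out.grad
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, self.data.shape) / n)

        out._backward = _bw
        return out

    def reshape(self, *shape: int) -> "Tensor":
        out = _make(self.data.reshape(shape), (self,))
        out._backward = lambda: self._accumulate(out.grad.reshape(self.data.shape))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = _make(self.data[idx], (self,))

        def _bw():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accumulate(g)

        out._backward = _bw
        return out


def _make(data: Array, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(parents)
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def _bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(int(lo), int(hi))
            t._accumulate(out.grad[tuple(sl)])

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------


def _im2col(x: Array, kh: int, kw: int, stride: int, pad: int):
    """Return (cols, out_h, out_w); cols has shape (B*Ho*Wo, C*kh*kw)."""
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - kh) // stride + 1
    wo = (x.shape[3] - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    # windows laid out directly as (B, Ho, Wo, C, kh, kw): one cheap copy
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, ho, wo, c, kh, kw),
        strides=(s0, s2 * stride, s3 * stride, s1, s2, s3),
        writeable=False,
    )
    cols = np.ascontiguousarray(windows)
    return cols.reshape(b * ho * wo, c * kh * kw), ho, wo


def _col2im(
    gcols: Array, x_shape: tuple, kh: int, kw: int, stride: int, pad: int
) -> Array:
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    gx = np.zeros((b, c, hp, wp))
    g = gcols.reshape(b, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += g[
                :, :, i, j
            ]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, NCHW layout; w has shape (F, C, kh, kw)."""
    f, c, kh, kw = w.data.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    batch = x.data.shape[0]
    y = cols @ w.data.reshape(f, -1).T
    if b is not None:
        y = y + b.data
    y = y.reshape(batch, ho, wo, f).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)
    out = _make(y, parents)

    def _bw():
        gy = out.grad.transpose(0, 2, 3, 1).reshape(-1, f)
        w._accumulate((gy.T @ cols).reshape(w.data.shape))
        if b is not None:
            b._accumulate(gy.sum(axis=0))
        gcols = gy @ w.data.reshape(f, -1)
        x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, pad))

    out._backward = _bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour spatial upsampling by 2 (NCHW)."""
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = _make(y, (x,))

    def _bw():
        b, c, h2, w2 = out.grad.shape
        g = out.grad.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        x._accumulate(g)

    out._backward = _bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C) spatial mean."""
    return x.mean_axes((2, 3), keepdims=False)


# ---------------------------------------------------------------------------
# layers and optimizer
# ---------------------------------------------------------------------------


class Conv2d:
    """Convolution layer with He-style initialization from a seeded RNG."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.w = Tensor(
            rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel)),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride = stride
        self.pad = pad
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    @property
    def parameters(self) -> list[Tensor]:
        return [self.w, self.b]


class Adam:
    """Adam with an externally supplied learning rate per step."""

    def __init__(
        self,
        params: Sequence[Tensor],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float64).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64).copy() for v in state["v"]]
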