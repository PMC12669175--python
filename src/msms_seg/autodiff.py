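"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation network in this package is small enough to train on a CPU,
so instead of a heavyweight deep-learning framework it runs on this compact
tape-based engine: a :class:`Tensor` wraps an ``ndarray`` and records, for
each produced value, closures that map the output gradient to parent
gradients.  Only the primitives the network actually needs are provided
(broadcast arithmetic, einsum, reductions, elementwise nonlinearities,
3-D unfold for convolutions, axis permutations for the scan serialization,
and a first-order linear recurrence used by the selective scan).

The linear recurrence ``h[n] = a[n] * h[n-1] + b[n]`` is evaluated with a
chunked two-pass algorithm (vectorized within chunks, sequential across
chunk summaries), which is algebraically identical to the naive loop — the
execution strategy never changes the result beyond float rounding.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "Parameter", "linear_recurrence", "AdamW"]


# ---------------------------------------------------------------------------
# Tensor core


class Tensor:
    """An ndarray with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        # list of (parent Tensor, fn: out_grad -> parent_grad_contribution)
        self._parents: list[tuple["Tensor", Callable[[np.ndarray], np.ndarray]]] = []

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- graph -------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p, _ in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, fn in node._parents:
                contrib = fn(g)
                if parent.grad is None:
                    parent.grad = contrib.copy() if contrib.base is not None else contrib
                else:
                    parent.grad = parent.grad + contrib

    def zero_grad(self) -> None:
        self.grad = None

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def _make(self, data, parents) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p, _ in parents):
            out.requires_grad = True
            out._parents = [p for p in parents]
        return out

    # -- broadcast arithmetic ----------------------------------------------

    def __add__(self, other):
        o = self._wrap(other)
        data = self.data + o.data
        return self._make(
            data,
            [
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (o, lambda g: _unbroadcast(g, o.data.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        o = self._wrap(other)
        data = self.data * o.data
        return self._make(
            data,
            [
                (self, lambda g: _unbroadcast(g * o.data, self.data.shape)),
                (o, lambda g: _unbroadcast(g * self.data, o.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._wrap(other)
        data = self.data / o.data
        return self._make(
            data,
            [
                (self, lambda g: _unbroadcast(g / o.data, self.data.shape)),
                (o, lambda g: _unbroadcast(-g * self.data / (o.data**2), o.data.shape)),
            ],
        )

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, k: float):
        data = self.data**k
        return self._make(data, [(self, lambda g: g * k * self.data ** (k - 1))])

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        return self._make(data, [(self, grad_fn)])

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else _axis_size(self.data.shape, axis)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ----------------------------------------------------------

    def reshape(self, shape, order: str = "C"):
        data = self.data.reshape(shape, order=order)
        src_shape = self.data.shape
        return self._make(
            data, [(self, lambda g: g.reshape(src_shape, order=order))]
        )

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        return self._make(
            self.data.transpose(axes), [(self, lambda g: g.transpose(inv))]
        )

    # -- elementwise nonlinearities -----------------------------------------

    def exp(self):
        data = np.exp(self.data)
        return self._make(data, [(self, lambda g: g * data)])

    def log(self):
        return self._make(np.log(self.data), [(self, lambda g: g / self.data)])

    def sqrt(self):
        data = np.sqrt(self.data)
        return self._make(data, [(self, lambda g: g * 0.5 / data)])

    def leaky_relu(self, slope: float = 0.01):
        pos = self.data > 0
        data = np.where(pos, self.data, slope * self.data)
        return self._make(data, [(self, lambda g: g * np.where(pos, 1.0, slope))])

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        return self._make(x * cdf, [(self, lambda g: g * (cdf + x * pdf))])

    def softplus(self):
        # stable: log(1 + e^x) = max(x, 0) + log1p(e^{-|x|})
        x = self.data
        data = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
        sig = 1.0 / (1.0 + np.exp(-x))
        return self._make(data, [(self, lambda g: g * sig)])

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(data, [(self, lambda g: g * data * (1.0 - data))])


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _axis_size(shape: tuple, axis) -> int:
    if isinstance(axis, int):
        return shape[axis]
    return int(np.prod([shape[a] for a in axis]))


class Parameter(Tensor):
    """A leaf tensor optimized during training.

    ``decay=False`` marks parameters exempt from weight decay (biases,
    normalization affines, state-matrix logs).
    """

    def __init__(self, data, decay: bool = True):
        super().__init__(np.array(data, dtype=np.float64), requires_grad=True)
        self.decay = decay


# ---------------------------------------------------------------------------
# Structured ops


def einsum(subscripts: str, *tensors: Tensor) -> Tensor:
    """Differentiable einsum (no repeated indices within one operand)."""
    ts = [Tensor._wrap(t) for t in tensors]
    ins, out_sub = subscripts.replace(" ", "").split("->")
    in_subs = ins.split(",")
    data = np.einsum(subscripts, *[t.data for t in ts])
    parents = []
    for i, t in enumerate(ts):
        others_sub = [in_subs[j] for j in range(len(ts)) if j != i]
        others = [ts[j] for j in range(len(ts)) if j != i]
        back_sub = ",".join([out_sub] + others_sub) + "->" + in_subs[i]

        def fn(g, back_sub=back_sub, others=others):
            return np.einsum(back_sub, g, *[o.data for o in others])

        parents.append((t, fn))
    return ts[0]._make(data, parents)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    ts = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    parents = []
    start = 0
    for t in ts:
        n = t.data.shape[axis]
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(start, start + n)
        sl = tuple(sl)
        parents.append((t, lambda g, sl=sl: g[sl]))
        start += n
    return ts[0]._make(data, parents)


def pad_spatial(t: Tensor, pads: Sequence[tuple[int, int]]) -> Tensor:
    """Zero-pad; ``pads`` gives (before, after) per axis."""
    pads = [tuple(p) for p in pads]
    data = np.pad(t.data, pads)
    sl = tuple(slice(b, b + s) for (b, _), s in zip(pads, t.data.shape))
    return t._make(data, [(t, lambda g: g[sl])])


def crop(t: Tensor, slices: Sequence[slice]) -> Tensor:
    sl = tuple(slices)
    data = t.data[sl]

    def fn(g):
        out = np.zeros_like(t.data)
        out[sl] = g
        return out

    return t._make(data, [(t, fn)])


def permute_last(t: Tensor, idx: np.ndarray, inv_idx: np.ndarray) -> Tensor:
    """Bijective gather along the last axis: ``y[..., j] = x[..., idx[j]]``."""
    data = t.data[..., idx]
    return t._make(data, [(t, lambda g: g[..., inv_idx])])


def unfold3d(
    t: Tensor, kernel: tuple[int, int, int], stride: tuple[int, int, int]
) -> Tensor:
    """Extract sliding 3-D patches with same-padding.

    Input ``(C, X, Y, Z)`` -> output ``(C, K, Xo, Yo, Zo)`` where
    ``K = kx*ky*kz`` and ``Xo = ceil(X / sx)`` etc.
    """
    C, X, Y, Z = t.data.shape
    kx, ky, kz = kernel
    sx, sy, sz = stride
    pads = [(0, 0)] + [_same_pads(n, k, s) for n, k, s in zip((X, Y, Z), kernel, stride)]
    padded = np.pad(t.data, pads)
    out_shape = tuple(-(-n // s) for n, s in zip((X, Y, Z), stride))
    K = kx * ky * kz
    out = np.empty((C, K) + out_shape, dtype=t.data.dtype)
    offsets = [(dx, dy, dz) for dz in range(kz) for dy in range(ky) for dx in range(kx)]
    # offset index k is x-fastest to match weight layout
    for k, (dx, dy, dz) in enumerate(offsets):
        out[:, k] = padded[
            :,
            dx : dx + out_shape[0] * sx : sx,
            dy : dy + out_shape[1] * sy : sy,
            dz : dz + out_shape[2] * sz : sz,
        ]

    def fn(g):
        gpad = np.zeros_like(padded)
        for k, (dx, dy, dz) in enumerate(offsets):
            gpad[
                :,
                dx : dx + out_shape[0] * sx : sx,
                dy : dy + out_shape[1] * sy : sy,
                dz : dz + out_shape[2] * sz : sz,
            ] += g[:, k]
        sl = tuple(
            slice(b, b + n) for (b, _), n in zip(pads, (C, X, Y, Z))
        )
        return gpad[sl]

    return t._make(out, [(t, fn)])


def _same_pads(n: int, k: int, s: int) -> tuple[int, int]:
    out = -(-n // s)
    total = max((out - 1) * s + k - n, 0)
    lo = total // 2
    return lo, total - lo


# ---------------------------------------------------------------------------
# First-order linear recurrence (the scan primitive)


def linear_recurrence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Evaluate ``h[n] = a[n] * h[n-1] + b[n]`` with ``h[-1] = 0`` along axis 0.

    Chunked two-pass evaluation: local solutions and running products are
    computed with a short vectorized loop inside each chunk, chunk boundary
    states are chained sequentially, and the boundary state is propagated
    back into every chunk.  Exactly equivalent to the naive loop.
    """
    L = a.shape[0]
    if L == 0:
        return np.zeros_like(b)
    S = max(1, int(math.sqrt(L)))
    nc = -(-L // S)
    pad = nc * S - L
    tail = a.shape[1:]
    if pad:
        a = np.concatenate([a, np.zeros((pad,) + tail, a.dtype)], axis=0)
        b = np.concatenate([b, np.zeros((pad,) + tail, b.dtype)], axis=0)
    ac = a.reshape((nc, S) + tail)
    bc = b.reshape((nc, S) + tail)
    h_loc = np.empty_like(bc)  # local solution with zero chunk-entry state
    p_run = np.empty_like(ac)  # running product of a within the chunk
    h = np.zeros((nc,) + tail, dtype=b.dtype)
    p = np.ones((nc,) + tail, dtype=a.dtype)
    for s in range(S):
        h = ac[:, s] * h + bc[:, s]
        p = p * ac[:, s]
        h_loc[:, s] = h
        p_run[:, s] = p
    # chain chunk-entry states sequentially
    h0 = np.zeros((nc,) + tail, dtype=b.dtype)
    state = np.zeros(tail, dtype=b.dtype)
    for c in range(nc):
        h0[c] = state
        state = h_loc[c, -1] + p_run[c, -1] * state
    out = h_loc + p_run * h0[:, None]
    return out.reshape((nc * S,) + tail)[:L]


def linear_scan(a: Tensor, b: Tensor) -> Tensor:
    """Differentiable first-order recurrence along axis 0."""
    h = linear_recurrence(a.data, b.data)
    cache: list = [None, None]  # [g, lam] of the latest gradient pass

    def adjoint(g):
        # lam[n] = g[n] + a[n+1] * lam[n+1]  (reverse recurrence)
        if cache[0] is not g:
            a_shift = np.concatenate(
                [a.data[1:], np.ones((1,) + a.data.shape[1:])], axis=0
            )
            cache[0] = g
            cache[1] = linear_recurrence(a_shift[::-1], g[::-1])[::-1]
        return cache[1]

    def fn_a(g):
        lam = adjoint(g)
        h_prev = np.concatenate([np.zeros((1,) + h.shape[1:]), h[:-1]], axis=0)
        return lam * h_prev

    def fn_b(g):
        return adjoint(g)

    return a._make(h, [(a, fn_a), (b, fn_b)])


# ---------------------------------------------------------------------------
# Module base


class Module:
    """Base class for layers: recursive parameter collection."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()
        for v in vars(self).values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for it in items:
                if isinstance(it, Parameter) and id(it) not in seen:
                    seen.add(id(it))
                    out.append(it)
                elif isinstance(it, Module):
                    for p in it.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            out.append(p)
        return out

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat name -> array mapping for checkpointing."""
        out: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            items = list(enumerate(v)) if isinstance(v, (list, tuple)) else [("", v)]
            for key, it in items:
                full = f"{prefix}{name}{key if key == '' else f'.{key}'}"
                if isinstance(it, Parameter):
                    out[full] = it.data
                elif isinstance(it, Module):
                    out.update(it.state_arrays(full + "."))
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in vars(self).items():
            items = list(enumerate(v)) if isinstance(v, (list, tuple)) else [("", v)]
            for key, it in items:
                full = f"{prefix}{name}{key if key == '' else f'.{key}'}"
                if isinstance(it, Parameter):
                    it.data = np.array(state[full], dtype=np.float64)
                elif isinstance(it, Module):
                    it.load_state_arrays(state, full + ".")


# ---------------------------------------------------------------------------
# Optimizer


class AdamW:
    """AdamW with decoupled weight decay.

    Decay is applied to matrix/kernel weights only; vector parameters
    (biases, normalization gains, per-channel state-matrix logs) are
    exempt, the usual convention.  ``clip_norm`` bounds the global
    gradient norm before each update.
    """

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.05,
        clip_norm: float | None = 1.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def _clip(self) -> None:
        if self.clip_norm is None:
            return
        total = math.sqrt(
            sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None)
        )
        if total > self.clip_norm:
            scale = self.clip_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * scale

    def step(self) -> None:
        self._clip()
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            wd = self.weight_decay if getattr(p, "decay", True) else 0.0
            p.data -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + wd * p.data
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
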