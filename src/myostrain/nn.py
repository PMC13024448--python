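"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module provides exactly the primitives the displacement-regression
networks need — 5-D tensors (batch, channel, time, row, col), dilated 3-D
convolution, spatial max-pooling and nearest upsampling, batch
normalization, elementwise activations, and fused displacement-loss ops —
together with an RMSprop optimizer.  Gradients are accumulated on a tape of
:class:`Tensor` nodes and released after ``backward``.

Everything is deterministic: no threading tricks, no atomics, plain numpy
reductions, so two runs from the same seed produce bit-identical results.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "conv3d",
    "maxpool_hw",
    "upsample_hw",
    "concat_channels",
    "add",
    "relu",
    "tanh",
    "sigmoid",
    "BatchNorm3d",
    "RMSprop",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple = (),
        backward: Callable | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def needs_grad(self) -> bool:
        """True if this node requires a gradient or sits on a grad path."""
        return self.requires_grad or bool(self._parents)

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        """Reverse-mode sweep from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs must not hit the recursion limit
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
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
                t.grad = None if t is not self and not t.requires_grad else t.grad
        # intermediate grads are dropped above to bound memory; parameter and
        # explicitly-requested grads survive.


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad = t.grad + g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None, dilation: Sequence[int] = (1, 1, 1)) -> Tensor:
    """'Same'-padded 3-D convolution.

    ``x``: (N, Ci, T, H, W); ``w``: (Co, Ci, kt, kh, kw); ``b``: (Co,).
    Kernel taps are looped explicitly (kernels here are tiny: at most 9
    taps) and each tap is a channel contraction, which numpy dispatches to
    BLAS via einsum.
    """
    N, Ci, T, H, W = x.data.shape
    Co, Ci_w, kt, kh, kw = w.data.shape
    if Ci_w != Ci:
        raise ValueError(f"conv3d: input has {Ci} channels, kernel expects {Ci_w}")
    dt, dh, dw = dilation
    pt, ph, pw = dt * (kt - 1) // 2, dh * (kh - 1) // 2, dw * (kw - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
    out = np.zeros((N, Co, T, H, W), dtype=x.data.dtype)
    taps = [(a, c, e) for a in range(kt) for c in range(kh) for e in range(kw)]
    for a, c, e in taps:
        xs = xp[:, :, a * dt:a * dt + T, c * dh:c * dh + H, e * dw:e * dw + W]
        out += np.einsum("oi,nithw->nothw", w.data[:, :, a, c, e], xs, optimize=True)
    if b is not None:
        out += b.data[None, :, None, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def _bw(g: np.ndarray) -> None:
        if b is not None and b.needs_grad:
            _accum(b, g.sum(axis=(0, 2, 3, 4)))
        gw = np.zeros_like(w.data) if w.needs_grad else None
        gxp = np.zeros_like(xp) if x.needs_grad else None
        for a, c, e in taps:
            sl = (
                slice(None), slice(None),
                slice(a * dt, a * dt + T),
                slice(c * dh, c * dh + H),
                slice(e * dw, e * dw + W),
            )
            if gw is not None:
                gw[:, :, a, c, e] = np.einsum("nothw,nithw->oi", g, xp[sl], optimize=True)
            if gxp is not None:
                gxp[sl] += np.einsum("oi,nothw->nithw", w.data[:, :, a, c, e], g, optimize=True)
        if gw is not None:
            _accum(w, gw)
        if gxp is not None:
            _accum(x, gxp[:, :, pt:pt + T, ph:ph + H, pw:pw + W])

    return Tensor(out, parents=parents, backward=_bw)


# ---------------------------------------------------------------------------
# Pooling / upsampling / concat
# ---------------------------------------------------------------------------

def maxpool_hw(x: Tensor) -> Tensor:
    """2x2 max pool over the spatial axes only; time is never pooled."""
    N, C, T, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool_hw: H and W must be even, got {H}x{W}")
    r = x.data.reshape(N, C, T, H // 2, 2, W // 2, 2)
    rr = r.transpose(0, 1, 2, 3, 5, 4, 6).reshape(N, C, T, H // 2, W // 2, 4)
    idx = rr.argmax(axis=-1)
    out = np.take_along_axis(rr, idx[..., None], axis=-1)[..., 0]

    def _bw(g: np.ndarray) -> None:
        if not x.needs_grad:
            return
        gr = np.zeros_like(rr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = (
            gr.reshape(N, C, T, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 3, 5, 4, 6)
            .reshape(N, C, T, H, W)
        )
        _accum(x, gx)

    return Tensor(out, parents=(x,), backward=_bw)


def upsample_hw(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of the spatial axes."""
    N, C, T, H, W = x.data.shape
    out = x.data.repeat(2, axis=3).repeat(2, axis=4)

    def _bw(g: np.ndarray) -> None:
        if x.needs_grad:
            _accum(x, g.reshape(N, C, T, H, 2, W, 2).sum(axis=(4, 6)))

    return Tensor(out, parents=(x,), backward=_bw)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    Ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def _bw(g: np.ndarray) -> None:
        if a.needs_grad:
            _accum(a, g[:, :Ca])
        if b.needs_grad:
            _accum(b, g[:, Ca:])

    return Tensor(out, parents=(a, b), backward=_bw)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def _bw(g: np.ndarray) -> None:
        if a.needs_grad:
            _accum(a, g)
        if b.needs_grad:
            _accum(b, g)

    return Tensor(out, parents=(a, b), backward=_bw)


# ---------------------------------------------------------------------------
# Activations
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0)

    def _bw(g: np.ndarray) -> None:
        if x.needs_grad:
            _accum(x, g * (x.data > 0))

    return Tensor(out, parents=(x,), backward=_bw)


def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.data)

    def _bw(g: np.ndarray) -> None:
        if x.needs_grad:
            _accum(x, g * (1.0 - out * out))

    return Tensor(out, parents=(x,), backward=_bw)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.data))

    def _bw(g: np.ndarray) -> None:
        if x.needs_grad:
            _accum(x, g * out * (1.0 - out))

    return Tensor(out, parents=(x,), backward=_bw)


# ---------------------------------------------------------------------------
# Batch normalization
# ---------------------------------------------------------------------------

class BatchNorm3d:
    """Per-channel batch normalization over (N, T, H, W).

    Training mode normalizes with batch statistics and updates running
    estimates; evaluation mode uses the running estimates, making the
    forward pass deterministic and input-independent in its statistics.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum
        self.training = True

    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        bshape = (1, -1, 1, 1, 1)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mu = self.running_mean
            var = self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu.reshape(bshape)) * inv.reshape(bshape)
        out = self.gamma.data.reshape(bshape) * xhat + self.beta.data.reshape(bshape)
        gamma, beta, training = self.gamma, self.beta, self.training

        def _bw(g: np.ndarray) -> None:
            if beta.needs_grad:
                _accum(beta, g.sum(axis=axes))
            if gamma.needs_grad:
                _accum(gamma, (g * xhat).sum(axis=axes))
            if not x.needs_grad:
                return
            gxh = g * gamma.data.reshape(bshape)
            if training:
                n = x.data.size / x.data.shape[1]
                # standard batch-norm backward: statistics depend on x
                gx = (
                    gxh
                    - gxh.mean(axis=axes).reshape(bshape)
                    - xhat * (gxh * xhat).mean(axis=axes).reshape(bshape)
                ) * inv.reshape(bshape)
                del n
            else:
                gx = gxh * inv.reshape(bshape)
            _accum(x, gx)

        return Tensor(out, parents=(x, gamma, beta), backward=_bw)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class RMSprop:
    """RMSprop with the conventional defaults (alpha=0.99, eps=1e-8)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 alpha: float = 0.99, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self._sq = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, s in zip(self.params, self._sq):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            s *= self.alpha
            s += (1.0 - self.alpha) * g * g
            p.data = (p.data - self.lr * g / (np.sqrt(s) + self.eps)).astype(p.data.dtype)
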