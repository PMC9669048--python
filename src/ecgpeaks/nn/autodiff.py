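"""Minimal reverse-mode autodiff on numpy arrays for 1-D convolutional nets.

Only the primitives the peak-detection network needs are implemented:
1-D convolution (full / pointwise / depthwise, with stride and dilation),
batch normalization, ELU, sigmoid, residual add, channel concatenation,
linear upsampling by an integer factor, and segment-mean pooling.  Each op
returns a :class:`Tensor` carrying a closure that maps the output gradient
to parent gradients; ``backward`` walks the graph in reverse topological
order.  Linear upsampling exploits the identity triangle = box * box, so
both directions run in O(n) via cumulative sums.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph construction (inference / validation passes)."""
    global grad_enabled
    prev = grad_enabled
    grad_enabled = False
    try:
        yield
    finally:
        grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False):
        self.data = data
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad = None

    @property
    def shape(self):
        return self.data.shape


def _node(data, parents, backward_fn):
    if not grad_enabled:
        return Tensor(data)
    return Tensor(data, parents, backward_fn)


def backward(root: Tensor, grad: np.ndarray) -> None:
    """Accumulate gradients of `root` w.r.t. every reachable parameter."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    root.grad = grad
    for node in reversed(topo):
        if node.backward_fn is None or node.grad is None:
            continue
        grads = node.backward_fn(node.grad)
        for p, g in zip(node.parents, grads):
            if g is None or not p.requires_grad:
                continue
            p.grad = g if p.grad is None else p.grad + g
        if node is not root:
            node.grad = None


# ---------------------------------------------------------------------------
# Elementwise / structural ops
# ---------------------------------------------------------------------------

def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    neg_part = np.expm1(np.minimum(x.data, 0.0))
    out = np.maximum(x.data, 0.0)
    out += alpha * neg_part

    def bwd(gy):
        # slope = alpha*exp(x) for x <= 0 and 1 for x > 0; with alpha = 1 both
        # branches equal neg_part + 1 because neg_part vanishes for x > 0
        if alpha == 1.0:
            return (gy * (neg_part + 1.0),)
        slope = np.where(x.data > 0, np.asarray(1.0, gy.dtype), alpha * neg_part + alpha)
        return (gy * slope,)

    return _node(out, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))

    def bwd(gy):
        return (gy * out * (1.0 - out),)

    return _node(out, (x,), bwd)


def add(a: Tensor, b: Tensor) -> Tensor:
    def bwd(gy):
        return gy, gy

    return _node(a.data + b.data, (a, b), bwd)


def squeeze_channel(x: Tensor) -> Tensor:
    """(B, 1, L) -> (B, L)."""
    if x.data.shape[1] != 1:
        raise ValueError("expected a single channel")

    def bwd(gy):
        return (gy[:, None, :],)

    return _node(x.data[:, 0, :], (x,), bwd)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(gy):
        return tuple(np.split(gy, splits, axis=axis))

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# Convolutions (inputs are (B, C, L))
# ---------------------------------------------------------------------------

def conv1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, dilation: int = 1) -> Tensor:
    """Dense (all-channel) 1-D convolution, 'same' padding before striding."""
    cout, cin, k = w.data.shape
    if k == 1 and stride == 1:
        return _pointwise(x, w, b)
    B, _, L = x.data.shape
    pad = dilation * (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    lout = (L + 2 * pad - dilation * (k - 1) - 1) // stride + 1
    idx = (np.arange(lout) * stride)[None, :] + (np.arange(k) * dilation)[:, None]
    cols = xp[:, :, idx].reshape(B, cin * k, lout)
    w2 = w.data.reshape(cout, cin * k)
    y = np.matmul(w2, cols)
    if b is not None:
        y += b.data[:, None]

    def bwd(gy):
        gw = np.matmul(gy, cols.transpose(0, 2, 1)).sum(axis=0).reshape(w.data.shape)
        gb = gy.sum(axis=(0, 2)) if b is not None else None
        gcols = np.matmul(w2.T, gy).reshape(B, cin, k, lout)
        gxp = np.zeros_like(xp)
        for j in range(k):
            gxp[:, :, j * dilation : j * dilation + stride * lout : stride] += gcols[:, :, j, :]
        gx = gxp[:, :, pad : pad + L] if pad else gxp
        return (gx, gw) if b is None else (gx, gw, gb)

    parents = (x, w) if b is None else (x, w, b)
    return _node(y, parents, bwd)


def _pointwise(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    B, cin, L = x.data.shape
    w2 = w.data[:, :, 0]
    if L >= 256:
        # per-sample GEMMs are already large; avoid transpose copies
        y = np.matmul(w2, x.data)
        if b is not None:
            y += b.data[:, None]

        def bwd(gy):
            gw = np.einsum("bot,bct->oc", gy, x.data, optimize=True)[:, :, None]
            gb = gy.sum(axis=(0, 2)) if b is not None else None
            gx = np.matmul(w2.T, gy)
            return (gx, gw) if b is None else (gx, gw, gb)

        return _node(y, (x, w) if b is None else (x, w, b), bwd)

    # short sequences: fold batch and length into one big GEMM
    xt = np.ascontiguousarray(x.data.transpose(1, 0, 2)).reshape(cin, B * L)
    y = np.ascontiguousarray(np.matmul(w2, xt).reshape(-1, B, L).transpose(1, 0, 2))
    if b is not None:
        y += b.data[:, None]

    def bwd(gy):
        gyt = np.ascontiguousarray(gy.transpose(1, 0, 2)).reshape(-1, B * L)
        gw = np.matmul(gyt, xt.T)[:, :, None]
        gb = gy.sum(axis=(0, 2)) if b is not None else None
        gx = np.ascontiguousarray(np.matmul(w2.T, gyt).reshape(cin, B, L).transpose(1, 0, 2))
        return (gx, gw) if b is None else (gx, gw, gb)

    return _node(y, (x, w) if b is None else (x, w, b), bwd)


def depthwise_conv1d(x: Tensor, w: Tensor, stride: int = 1, dilation: int = 1) -> Tensor:
    """Per-channel (depthwise) 1-D convolution; weight shape (C, k)."""
    B, C, L = x.data.shape
    _, k = w.data.shape
    pad = dilation * (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    lout = (L + 2 * pad - dilation * (k - 1) - 1) // stride + 1
    y = np.zeros((B, C, lout), dtype=x.data.dtype)
    for j in range(k):
        y += w.data[:, j, None] * xp[:, :, j * dilation : j * dilation + stride * lout : stride]

    def bwd(gy):
        gw = np.empty_like(w.data)
        gxp = np.zeros_like(xp)
        for j in range(k):
            sl = slice(j * dilation, j * dilation + stride * lout, stride)
            gw[:, j] = np.einsum("bct,bct->c", gy, xp[:, :, sl], optimize=True)
            gxp[:, :, sl] += w.data[:, j, None] * gy
        gx = gxp[:, :, pad : pad + L] if pad else gxp
        return gx, gw

    return _node(y, (x, w), bwd)


# ---------------------------------------------------------------------------
# Batch normalization
# ---------------------------------------------------------------------------

def batchnorm1d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    if training:
        mu = x.data.mean(axis=(0, 2), dtype=np.float64)
        var = np.einsum("bct,bct->c", x.data, x.data, optimize=True) / (
            x.data.shape[0] * x.data.shape[2]
        ) - mu * mu
        var = np.maximum(var, 0.0)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    std = np.sqrt(var + eps).astype(x.data.dtype)
    inv = (1.0 / std)[:, None]
    xhat = x.data * inv - (mu.astype(x.data.dtype)[:, None] * inv)
    y = gamma.data[:, None] * xhat + beta.data[:, None]

    def bwd(gy):
        gbeta = np.einsum("bct->c", gy, optimize=True)
        ggamma = np.einsum("bct,bct->c", gy, xhat, optimize=True)
        coef = gamma.data * inv[:, 0]
        if training:
            n = gy.shape[0] * gy.shape[2]
            gx = gy * coef[:, None]
            gx -= xhat * ((coef * ggamma / n)[:, None])
            gx -= (coef * gbeta / n)[:, None]
        else:
            gx = gy * coef[:, None]
        return gx, ggamma, gbeta

    return _node(y, (x, gamma, beta), bwd)


# ---------------------------------------------------------------------------
# Resampling ops
# ---------------------------------------------------------------------------

def upsample_linear(x: Tensor, factor: int) -> Tensor:
    """Length x `factor` linear interpolation (zero beyond the last sample).

    ``y[f*t + r] = (1 - r/f) x[t] + (r/f) x[t+1]`` with ``x[L] = 0``: input
    samples land exactly at multiples of `factor` with linear ramps between,
    and the tail ramps to zero.  The adjoint gathers each output block back
    onto its two supporting samples.
    """
    B, C, L = x.data.shape
    ramp = (np.arange(factor) / factor).astype(x.data.dtype)
    w0, w1 = 1.0 - ramp, ramp
    xn = np.zeros_like(x.data)
    xn[..., :-1] = x.data[..., 1:]
    y = (x.data[..., :, None] * w0 + xn[..., :, None] * w1).reshape(B, C, L * factor)

    def bwd(gy):
        g = gy.reshape(B, C, L, factor)
        gx = g @ w0
        tmp = g @ w1
        gx[..., 1:] += tmp[..., :-1]
        return (gx,)

    return _node(y, (x,), bwd)


def segment_pool(x: Tensor, seg: int) -> Tensor:
    """Mean over consecutive length-`seg` blocks, broadcast back (self-adjoint).

    A trailing partial block is averaged over its actual length.
    """

    def smooth(a):
        B, C, L = a.shape
        full = (L // seg) * seg
        out = np.empty_like(a)
        if full:
            m = a[..., :full].reshape(B, C, -1, seg).mean(axis=-1, keepdims=True)
            out[..., :full] = np.broadcast_to(m, (B, C, full // seg, seg)).reshape(B, C, full)
        if full < L:
            out[..., full:] = a[..., full:].mean(axis=-1, keepdims=True)
        return out

    def bwd(gy):
        return (smooth(gy),)

    return _node(smooth(x.data), (x,), bwd)
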